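import numpy as np
import pytest

from huffgap import (FacilityAttraction, ModelParams, StudyRegion,
                     draw_partial_variable, generate_region,
                     simulate_observed_totals)


@pytest.fixture
def toy_region() -> StudyRegion:
    """One area, two facilities, both at zero distance from the area."""
    return StudyRegion(
        facility_ids=["F0", "F1"],
        facility_coords=np.array([[51.0, 4.0], [51.0, 4.0]]),
        area_ids=["A0"],
        area_coords=np.array([[51.0, 4.0]]),
        distances=np.zeros((1, 2)),
        market_sizes=np.array([100]),
    )


def _random_instance(rng: np.random.Generator, n_areas: int, n_facilities: int):
    """A random small region + attraction pair for oracle comparisons."""
    region = StudyRegion(
        facility_ids=[f"F{j}" for j in range(n_facilities)],
        facility_coords=np.column_stack([
            rng.uniform(50.7, 51.5, n_facilities),
            rng.uniform(2.6, 5.9, n_facilities)]),
        area_ids=[f"A{i}" for i in range(n_areas)],
        area_coords=np.column_stack([
            rng.uniform(50.7, 51.5, n_areas), rng.uniform(2.6, 5.9, n_areas)]),
        distances=rng.uniform(0.0, 150.0, (n_areas, n_facilities)),
        market_sizes=rng.integers(10, 5000, n_areas),
    )
    avail = rng.integers(0, 2, n_facilities).astype(np.int8)
    attraction = FacilityAttraction(
        complete={"beds": rng.lognormal(np.log(300), 0.6, n_facilities)},
        partial={"reputation": np.maximum(rng.normal(10, 2.8, n_facilities), 0.01)},
        availability=avail,
    )
    params = ModelParams(
        gamma={"beds": rng.uniform(0.2, 1.5)},
        gamma_partial={"reputation": rng.uniform(0.1, 1.3)},
        decay=rng.uniform(0.0, 0.4),
        benchmark=rng.uniform(0.05, 1.0),
    )
    return region, attraction, params


@pytest.fixture
def random_instance():
    return _random_instance


@pytest.fixture(scope="session")
def small_market():
    """A modest synthetic market with simulated admissions, reused across
    estimator tests: 15 facilities, 300 areas, ~200k admissions."""
    region, base = generate_region(15, 300, total_market=200_000, seed=42)
    reputation = draw_partial_variable(15, seed=43)
    attraction = FacilityAttraction(
        dict(base.complete), {"reputation": reputation},
        np.ones(15, dtype=np.int8))
    truth = ModelParams(gamma={"beds": 0.92},
                        gamma_partial={"reputation": 0.7}, decay=0.15)
    _, observed = simulate_observed_totals(region, attraction, truth, seed=44)
    return region, attraction, truth, observed
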