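"""Synthetic study regions and admission data.

The generator emulates the structure of a regional hospital market: J
facility locations and I demand-area centroids scattered over a bounded
box of roughly Flanders-like extent, a bed-count size variable, a
reputation-like score drawn from Normal(10, 2.8), and discrete admissions
drawn per area from the model's multinomial choice probabilities.

Every routine takes an explicit seed and is bit-reproducible; separate
seeds for geography, variables, availability and demand draws allow the
common-random-numbers discipline used by the experiment harness (vary one
factor while every other draw stays literally identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gravity import ModelParams, predict
from .region import FacilityAttraction, StudyRegion, distance_matrix

__all__ = [
    "FLANDERS_LIKE_EXTENT",
    "SimulationConfig",
    "generate_region",
    "draw_partial_variable",
    "assign_availability",
    "simulate_demand",
    "simulate_observed_totals",
    "derive_seed",
]

#: (lat_min, lat_max, lon_min, lon_max) giving ~0-240 km pairwise distances,
#: comparable to the spread of hospital campuses across a Flanders-sized region.
FLANDERS_LIKE_EXTENT = (50.7, 51.5, 2.6, 5.9)


def derive_seed(base_seed: int, *keys: int) -> int:
    """Derive an independent child seed (< 2^31) from a base seed and keys.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so children with
    different key tuples are statistically independent and stable across
    platforms.
    """
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


@dataclass
class SimulationConfig:
    """Ground truth and generator settings for one simulated market.

    Defaults encode the study conditions: size exponent 0.92, reputation
    score ~ Normal(10, 2.8) floored at 0.01, exponential distance decay
    0.15 per km, and a market totalling about 600,000 admissions so that
    multinomial noise at facility level sits near the ~1% accuracy floor.
    """

    true_params: ModelParams = field(default_factory=lambda: ModelParams(
        gamma={"beds": 0.92}, gamma_partial={"reputation": 0.7},
        decay=0.15, benchmark=1.0))
    n_facilities: int = 30
    n_areas: int = 1000
    extent: tuple[float, float, float, float] = FLANDERS_LIKE_EXTENT
    beds_median: float = 300.0
    beds_sigma: float = 0.6
    beds_floor: float = 30.0
    total_market: int = 600_000
    market_sigma: float = 1.0
    reputation_mean: float = 10.0
    reputation_sd: float = 2.8
    reputation_floor: float = 0.01
    availability_fraction: float = 1.0
    geography_seed: int = 0
    variables_seed: int = 1
    availability_seed: int = 2
    demand_seed: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.availability_fraction <= 1.0):
            raise ValueError("availability_fraction must lie in [0, 1]")
        if self.reputation_sd <= 0:
            raise ValueError("reputation_sd must be positive")


def generate_region(n_facilities: int, n_areas: int,
                    extent: tuple[float, float, float, float] = FLANDERS_LIKE_EXTENT,
                    *, beds_median: float = 300.0, beds_sigma: float = 0.6,
                    beds_floor: float = 30.0, total_market: int = 600_000,
                    market_sigma: float = 1.0, seed: int = 0,
                    ) -> tuple[StudyRegion, FacilityAttraction]:
    """Draw a synthetic study region with a bed-count attraction variable.

    Facility and area coordinates are uniform in the bounding box. Bed
    counts are lognormal around ``beds_median`` (floored at ``beds_floor``);
    area market sizes are lognormal, scaled to sum to ``total_market`` and
    rounded to integers. ``beds_sigma = 0`` or ``market_sigma = 0`` give
    constant values.

    Returns the region plus a :class:`FacilityAttraction` holding only the
    complete ``beds`` variable (partial variables are attached separately).
    """
    if n_facilities < 2:
        raise ValueError("need at least 2 facilities")
    if n_areas < 1:
        raise ValueError("need at least 1 area")
    lat_min, lat_max, lon_min, lon_max = extent
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    fac_lat = rng.uniform(lat_min, lat_max, n_facilities)
    fac_lon = rng.uniform(lon_min, lon_max, n_facilities)
    area_lat = rng.uniform(lat_min, lat_max, n_areas)
    area_lon = rng.uniform(lon_min, lon_max, n_areas)
    if beds_sigma > 0:
        beds = beds_median * rng.lognormal(0.0, beds_sigma, n_facilities)
    else:
        beds = np.full(n_facilities, float(beds_median))
    beds = np.maximum(beds, beds_floor)
    if market_sigma > 0:
        weights = rng.lognormal(0.0, market_sigma, n_areas)
    else:
        weights = np.ones(n_areas)
    sizes = weights / weights.sum() * float(total_market)
    market = np.maximum(np.rint(sizes).astype(np.int64), 0)

    facility_coords = np.column_stack([fac_lat, fac_lon])
    area_coords = np.column_stack([area_lat, area_lon])
    region = StudyRegion(
        facility_ids=[f"F{j:03d}" for j in range(n_facilities)],
        facility_coords=facility_coords,
        area_ids=[f"A{i:05d}" for i in range(n_areas)],
        area_coords=area_coords,
        distances=distance_matrix(area_coords, facility_coords),
        market_sizes=market,
    )
    attraction = FacilityAttraction(complete={"beds": beds})
    return region, attraction


def draw_partial_variable(n_facilities: int, mean: float = 10.0, sd: float = 2.8,
                          floor: float = 0.01, seed: int = 0) -> np.ndarray:
    """Draw a reputation-like score: Normal(mean, sd) clipped below at ``floor``.

    The clip keeps the power utility defined; at the default (10, 2.8) it
    touches roughly 2 draws in 10,000.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if floor <= 0:
        raise ValueError("floor must be positive")
    rng = np.random.default_rng(seed)
    return np.maximum(rng.normal(mean, sd, n_facilities), floor)


def assign_availability(n_facilities: int, p: float, seed: int = 0,
                        nested: bool = True) -> np.ndarray:
    """Binary availability vector B with exactly round(p*J) ones (half-up).

    With ``nested=True`` the selected facilities at a smaller p are a subset
    of those at any larger p under the same seed: a fixed random priority
    order is drawn once and the first round(p*J) facilities are flagged.
    ``nested=False`` draws an independent subset per call.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    k = int(np.floor(p * n_facilities + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_facilities)
    if not nested:
        order = rng.permutation(n_facilities)  # second, independent order
    mask = np.zeros(n_facilities, dtype=np.int8)
    mask[order[:k]] = 1
    return mask


def simulate_demand(choice_probabilities: np.ndarray, market_sizes: np.ndarray,
                    seed: int = 0) -> np.ndarray:
    """Integer admission volumes V_ij: one multinomial draw per area.

    Each area i contributes V_i draws over the facilities with its row of
    choice probabilities as weights, so Σ_j V_ij = V_i exactly.
    """
    probs = np.asarray(choice_probabilities, dtype=float)
    sizes = np.asarray(market_sizes)
    if probs.ndim != 2:
        raise ValueError("choice probabilities must be an I×J matrix")
    if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each probability row must be non-negative and sum to 1")
    if np.any(sizes < 0):
        raise ValueError("market sizes must be non-negative")
    rng = np.random.default_rng(seed)
    # renormalize away float round-off so rng.multinomial accepts every row
    probs = probs / probs.sum(axis=1, keepdims=True)
    return rng.multinomial(sizes.astype(np.int64), probs)


def simulate_observed_totals(region: StudyRegion, attraction: FacilityAttraction,
                             true_params: ModelParams, seed: int = 0,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate admissions under the true model and return (V_ij, facility totals).

    The truth uses every attraction variable for every facility (full
    availability, no benchmark correction); incomplete availability is a
    property of what the *estimator* sees, not of the world.
    """
    full = attraction.with_availability(np.ones(region.n_facilities, dtype=np.int8))
    truth = ModelParams(gamma=dict(true_params.gamma),
                        gamma_partial=dict(true_params.gamma_partial),
                        decay=true_params.decay, benchmark=1.0)
    pred = predict(truth, region, full)
    volumes = simulate_demand(pred.shares, region.market_sizes, seed=seed)
    return volumes, volumes.sum(axis=0)
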