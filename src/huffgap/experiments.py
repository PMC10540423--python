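"""Simulation-study harness: the effect-size × availability grid.

One study generates a single synthetic market (geography, bed counts and
reputation scores drawn once), then sweeps a grid of reputation effect
sizes and availability fractions p. Variance between grid cells is
controlled with common random numbers:

* reputation values are drawn once and reused for every cell;
* within one (effect size, run) pair, the same demand realization is reused
  across every p — availability changes what the estimator sees, never the
  world;
* availability masks are nested in p (the in-group at p1 < p2 is a subset
  of the in-group at p2), drawn per run.

Each cell is fitted with the benchmark-adjusted model; per (effect size,
run) a control fit of the classic size-only model is added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import FitConfig, fit, fit_control_model
from .evaluation import grouped_accuracy, mape
from .gravity import ModelParams
from .region import FacilityAttraction, StudyRegion
from .synthetic import (SimulationConfig, assign_availability, derive_seed,
                        draw_partial_variable, generate_region,
                        simulate_observed_totals)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentGrid", "ExperimentResult", "StudySummary",
           "run_grid", "summarize", "default_availabilities"]

# seed namespace tags for derive_seed
_SEED_GEOGRAPHY, _SEED_VARIABLES, _SEED_AVAILABILITY, _SEED_DEMAND, _SEED_FIT, \
    _SEED_CONTROL = range(6)


def default_availabilities() -> tuple[float, ...]:
    """Availability grid 0.05, 0.10, ..., 1.00 (19 sub-unity values plus 1)."""
    return tuple(np.round(np.arange(1, 21) * 0.05, 2))


@dataclass
class ExperimentGrid:
    """Design of the simulation study.

    The defaults enumerate 7 effect sizes × 20 availability fractions ×
    5 runs = 700 fitting runs, of which 7 × 19 × 5 = 665 lie below full
    availability.
    """

    effect_sizes: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3)
    availabilities: tuple[float, ...] = field(default_factory=default_availabilities)
    runs_per_cell: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.effect_sizes and self.availabilities and self.runs_per_cell >= 1):
            raise ValueError("grid must be non-empty")

    @property
    def n_runs(self) -> int:
        return len(self.effect_sizes) * len(self.availabilities) * self.runs_per_cell

    @property
    def n_sub_unity_runs(self) -> int:
        below = sum(1 for p in self.availabilities if p < 1.0)
        return len(self.effect_sizes) * below * self.runs_per_cell

    def cells(self):
        """Yield every (effect_size, p, run) fitting run in execution order."""
        for e in self.effect_sizes:
            for run in range(self.runs_per_cell):
                for p in self.availabilities:
                    yield e, p, run


@dataclass
class ExperimentResult:
    """Per-run fit records plus control-model records and design metadata."""

    runs: pd.DataFrame
    control: pd.DataFrame
    grid: ExperimentGrid


def _study_inputs(grid: ExperimentGrid, sim: SimulationConfig,
                  ) -> tuple[StudyRegion, FacilityAttraction, str]:
    region, attraction = generate_region(
        sim.n_facilities, sim.n_areas, sim.extent,
        beds_median=sim.beds_median, beds_sigma=sim.beds_sigma,
        beds_floor=sim.beds_floor, total_market=sim.total_market,
        market_sigma=sim.market_sigma,
        seed=derive_seed(grid.base_seed, _SEED_GEOGRAPHY))
    partial_names = sorted(sim.true_params.gamma_partial)
    if len(partial_names) != 1:
        raise ValueError("the study design uses exactly one partial variable")
    name = partial_names[0]
    values = draw_partial_variable(
        sim.n_facilities, sim.reputation_mean, sim.reputation_sd,
        sim.reputation_floor, seed=derive_seed(grid.base_seed, _SEED_VARIABLES))
    attraction = FacilityAttraction(
        dict(attraction.complete), {name: values},
        np.ones(sim.n_facilities, dtype=np.int8))
    return region, attraction, name


def run_grid(grid: ExperimentGrid, sim: SimulationConfig | None = None,
             fit_config: FitConfig | None = None,
             out_dir=None) -> ExperimentResult:
    """Execute the full grid and return tidy per-run records.

    A failed fit is recorded with ``failed = True`` and NaN estimates; it
    never aborts the remaining cells. When ``out_dir`` is given, records are
    appended incrementally to ``runs.csv`` / ``control.csv`` there.
    """
    sim = sim or SimulationConfig()
    fit_config = fit_config or FitConfig()
    region, attraction, partial_name = _study_inputs(grid, sim)

    run_rows: list[dict] = []
    control_rows: list[dict] = []
    runs_path = control_path = None
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        runs_path, control_path = out / "runs.csv", out / "control.csv"

    for e_idx, effect in enumerate(grid.effect_sizes):
        truth = replace(sim.true_params,
                        gamma_partial={partial_name: float(effect)})
        for run in range(grid.runs_per_cell):
            demand_seed = derive_seed(grid.base_seed, _SEED_DEMAND, e_idx, run)
            _, observed = simulate_observed_totals(region, attraction, truth,
                                                   seed=demand_seed)
            avail_seed = derive_seed(grid.base_seed, _SEED_AVAILABILITY, run)

            ctrl_row = {"effect_size": effect, "run": run, "failed": False}
            try:
                ctrl_cfg = replace(fit_config,
                                   seed=derive_seed(grid.base_seed, _SEED_CONTROL,
                                                    e_idx, run))
                ctrl = fit_control_model(region, attraction, observed, ctrl_cfg)
                ctrl_pred = _predicted_totals(ctrl.params, region,
                                              attraction.drop_partial())
                ctrl_row.update({f"gamma_{k}": v for k, v in ctrl.params.gamma.items()})
                ctrl_row.update(decay=ctrl.params.decay, mse=ctrl.mse,
                                mape_all=mape(observed, ctrl_pred))
            except Exception:  # noqa: BLE001 - a cell failure must not kill the grid
                logger.exception("control fit failed (effect=%s run=%d)", effect, run)
                ctrl_row["failed"] = True
            control_rows.append(ctrl_row)
            _maybe_append(control_path, ctrl_row)

            for p in grid.availabilities:
                mask = assign_availability(region.n_facilities, p,
                                           seed=avail_seed, nested=True)
                row = {"effect_size": effect, "p": float(p), "run": run,
                       "failed": False}
                try:
                    cfg = replace(fit_config,
                                  seed=derive_seed(grid.base_seed, _SEED_FIT,
                                                   e_idx, run))
                    masked = attraction.with_availability(mask)
                    res = fit(region, masked, observed, cfg)
                    pred = _predicted_totals(res.params, region, masked)
                    acc = grouped_accuracy(observed, pred, mask)
                    row.update({f"gamma_{k}": v for k, v in res.params.gamma.items()})
                    row.update(
                        alpha=res.params.gamma_partial.get(partial_name, np.nan),
                        decay=res.params.decay, benchmark=res.params.benchmark,
                        mse=res.mse, mape_in=acc.mape_in, mape_out=acc.mape_out,
                        mape_all=acc.mape_all)
                except Exception:  # noqa: BLE001
                    logger.exception("fit failed (effect=%s p=%s run=%d)",
                                     effect, p, run)
                    row["failed"] = True
                run_rows.append(row)
                _maybe_append(runs_path, row)
            logger.info("completed effect=%s run=%d", effect, run)

    return ExperimentResult(runs=pd.DataFrame(run_rows),
                            control=pd.DataFrame(control_rows), grid=grid)


def _predicted_totals(params: ModelParams, region: StudyRegion,
                      attraction: FacilityAttraction) -> np.ndarray:
    from .gravity import predict
    return predict(params, region, attraction).facility_totals


def _maybe_append(path, row: dict) -> None:
    if path is None:
        return
    pd.DataFrame([row]).to_csv(path, mode="a", header=not path.exists(), index=False)


@dataclass
class StudySummary:
    """Aggregates of a grid run: accuracy table, control accuracy, the
    in-group improvement over the control model at a reference availability,
    and the effect-size vs fitted-benchmark records below full availability."""

    accuracy: pd.DataFrame
    control: pd.DataFrame
    improvement_by_effect: pd.DataFrame
    mean_improvement: float | None
    alpha_bm: pd.DataFrame
    alpha_bm_spearman: float | None

    def to_text(self) -> str:
        lines = ["Accuracy by effect size and availability (mean over runs, %):",
                 self.accuracy.to_string(), "",
                 "Control model (size only) MAPE by effect size (%):",
                 self.control.to_string(), ""]
        if self.mean_improvement is not None:
            lines += [f"Mean in-group MAPE improvement over control: "
                      f"{self.mean_improvement:.1f}%", ""]
        if self.alpha_bm_spearman is not None:
            lines += [f"Spearman correlation between true effect size and fitted "
                      f"benchmark (p < 1): {self.alpha_bm_spearman:.3f}"]
        return "\n".join(lines)


def summarize(results: ExperimentResult, reference_p: float = 0.25) -> StudySummary:
    """Aggregate grid records.

    Per (effect size, p): mean in/out/overall MAPE over runs. Per effect
    size: control MAPE. The improvement statistic is
    100 * (control − in-group) / control at ``reference_p``, averaged over
    effect sizes; it is ``None`` when the control MAPE is zero somewhere or
    no records exist at the reference availability.
    """
    runs = results.runs[~results.runs["failed"]]
    control = results.control[~results.control["failed"]]
    if runs.empty:
        raise ValueError("no successful runs to summarize")
    accuracy = (runs.groupby(["effect_size", "p"])
                [["mape_in", "mape_out", "mape_all"]].mean())
    control_tbl = (control.groupby("effect_size")[["mape_all", "mse"]]
                   .mean().rename(columns={"mape_all": "control_mape"}))

    at_ref = runs[np.isclose(runs["p"], reference_p)]
    improvement = pd.DataFrame()
    mean_improvement: float | None = None
    if not at_ref.empty and not control_tbl.empty:
        in_mape = at_ref.groupby("effect_size")["mape_in"].mean()
        joined = pd.concat([in_mape, control_tbl["control_mape"]], axis=1).dropna()
        valid = joined[joined["control_mape"] > 0]
        if len(valid):
            improvement = valid.assign(
                improvement_pct=100.0 * (valid["control_mape"] - valid["mape_in"])
                / valid["control_mape"])
            mean_improvement = float(improvement["improvement_pct"].mean())

    sub = runs[runs["p"] < 1.0].dropna(subset=["benchmark"])
    alpha_bm = sub[["effect_size", "p", "run", "alpha", "benchmark"]].copy()
    spearman: float | None = None
    if len(alpha_bm) >= 3 and alpha_bm["effect_size"].nunique() > 1:
        spearman = float(stats.spearmanr(alpha_bm["effect_size"],
                                         alpha_bm["benchmark"]).statistic)
    return StudySummary(accuracy=accuracy, control=control_tbl,
                        improvement_by_effect=improvement,
                        mean_improvement=mean_improvement,
                        alpha_bm=alpha_bm, alpha_bm_spearman=spearman)
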