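"""Fitting the adjusted gravity model to observed facility totals.

The model is nonlinear in its parameters and cannot be linearized, so it
is fitted by simulated annealing (:func:`scipy.optimize.dual_annealing`)
over box bounds, with an L-BFGS-B local refinement after each annealing
round, minimizing the mean squared error between observed and predicted
facility-level admission totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import dual_annealing

from .gravity import ModelParams, predict
from .region import FacilityAttraction, StudyRegion

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "objective_mse", "fit", "fit_control_model",
           "DEFAULT_BOUNDS"]

#: Box bounds per parameter kind; wide enough to cover realistic hospital
#: markets (size exponents near 1, decay well under 1/km) with margin.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (0.0, 3.0),
    "gamma_partial": (0.0, 3.0),
    "decay": (0.0, 1.0),
    "benchmark": (1e-4, 1.0),
}


@dataclass
class FitConfig:
    """Optimizer settings.

    ``annealing_iterations`` is the simulated-annealing global iteration
    budget (2000 reproduces the study's fitting process; desk-scale runs
    use fewer). ``local_search_max_iterations`` caps each L-BFGS-B
    refinement round. ``fixed_params`` pins named parameters (keys as in
    :meth:`ModelParams.as_dict`, e.g. ``"decay"`` or ``"gamma_beds"``) at a
    constant instead of fitting them.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    annealing_iterations: int = 2000
    local_search_max_iterations: int = 100
    seed: int = 0
    fixed_params: dict[str, float] = field(default_factory=dict)
    record_trace: bool = True

    def __post_init__(self) -> None:
        if self.annealing_iterations < 1 or self.local_search_max_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with low < high")


@dataclass
class FitResult:
    params: ModelParams
    mse: float
    objective_evaluations: int
    converged: bool
    trace: list[float] | None = None
    message: str = ""


def _build_params(x: np.ndarray, spec: list[tuple[str, str]],
                  fixed: dict[str, float],
                  complete_names: list[str], partial_names: list[str],
                  ) -> ModelParams:
    values = dict(fixed)
    for (key, _), v in zip(spec, x):
        values[key] = float(v)
    gamma = {n: values[f"gamma_{n}"] for n in complete_names}
    gamma_partial = {n: values[f"gamma_{n}"] for n in partial_names}
    return ModelParams(gamma=gamma, gamma_partial=gamma_partial,
                       decay=values["decay"], benchmark=values["benchmark"])


def objective_mse(params: ModelParams, region: StudyRegion,
                  attraction: FacilityAttraction,
                  observed_totals: np.ndarray) -> float:
    """Mean over facilities of squared (observed − predicted) totals."""
    observed = np.asarray(observed_totals, dtype=float)
    if np.any(observed < 0):
        raise ValueError("observed totals must be non-negative")
    pred = predict(params, region, attraction)
    resid = observed - pred.facility_totals
    return float(np.mean(resid ** 2))


def _free_parameter_spec(attraction: FacilityAttraction, config: FitConfig,
                         ) -> tuple[list[tuple[str, str]], dict[str, float]]:
    """Enumerate free parameters as (key, kind) pairs and implied fixings.

    The benchmark BM is identified only when availability is mixed: if every
    facility (or none) carries the partial variables, BM rescales all
    utilities of one homogeneous group and cancels in the shares, so it is
    pinned at 1 rather than left as a flat direction for the optimizer.
    """
    avail = attraction.availability
    fixed = dict(config.fixed_params)
    partial_names = sorted(attraction.partial)
    mixed = 0 < int(avail.sum()) < avail.shape[0]
    if not partial_names or not mixed:
        fixed.setdefault("benchmark", 1.0)
    spec: list[tuple[str, str]] = []
    for name in sorted(attraction.complete):
        spec.append((f"gamma_{name}", "gamma"))
    if int(avail.sum()) > 0:
        for name in partial_names:
            spec.append((f"gamma_{name}", "gamma_partial"))
    spec.append(("decay", "decay"))
    spec.append(("benchmark", "benchmark"))
    return [(k, kind) for k, kind in spec if k not in fixed], fixed


def fit(region: StudyRegion, attraction: FacilityAttraction,
        observed_totals: np.ndarray, config: FitConfig | None = None) -> FitResult:
    """Fit the model to facility-level observed totals.

    Runs one seeded annealing process over the configured bounds and keeps
    the bound-feasible parameter vector with the minimal MSE encountered
    (annealing proposals and local refinements included). Proposals with a
    non-finite objective are rejected, never propagated.
    """
    config = config or FitConfig()
    observed = np.asarray(observed_totals, dtype=float)
    if observed.shape != (region.n_facilities,):
        raise ValueError("observed totals must have one entry per facility")
    spec, fixed = _free_parameter_spec(attraction, config)
    if not spec:
        raise ValueError("no free parameters to fit")
    if region.n_facilities < len(spec):
        raise ValueError("need at least as many facilities as free parameters")
    complete_names = sorted(attraction.complete)
    partial_names = sorted(attraction.partial) if int(attraction.availability.sum()) else []
    bounds = [config.bounds[kind] for _, kind in spec]

    n_eval = 0
    best = {"f": np.inf, "x": None}

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        x = np.clip(x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        try:
            params = _build_params(x, spec, fixed, complete_names, partial_names)
            value = objective_mse(params, region, attraction, observed)
        except (ValueError, FloatingPointError):
            return 1e300
        if not np.isfinite(value):
            logger.debug("non-finite objective at %s rejected", x)
            return 1e300
        if value < best["f"]:
            best["f"] = value
            best["x"] = x.copy()
        return value

    trace: list[float] = []

    def callback(x, f, context):  # noqa: ANN001 - scipy callback signature
        if config.record_trace:
            trace.append(float(best["f"]))
        return False

    x0 = np.array([(lo + hi) / 2.0 for lo, hi in bounds])
    result = dual_annealing(
        objective, bounds=bounds, maxiter=config.annealing_iterations,
        minimizer_kwargs={
            "method": "L-BFGS-B",
            "options": {"maxiter": config.local_search_max_iterations},
        },
        rng=config.seed, x0=x0, callback=callback,
    )
    x_best = best["x"] if best["x"] is not None else np.asarray(result.x)
    params = _build_params(np.asarray(x_best), spec, fixed,
                           complete_names, partial_names)
    return FitResult(
        params=params,
        mse=float(best["f"]),
        objective_evaluations=n_eval,
        converged=bool(result.success),
        trace=trace if config.record_trace else None,
        message=str(result.message),
    )


def fit_control_model(region: StudyRegion, attraction: FacilityAttraction,
                      observed_totals: np.ndarray,
                      config: FitConfig | None = None) -> FitResult:
    """Fit the classic size-only gravity model (partial variables dropped).

    This is the model one is forced to use when incomplete variables are
    discarded: no partial exponents, benchmark pinned at 1.
    """
    return fit(region, attraction.drop_partial(), observed_totals, config)
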