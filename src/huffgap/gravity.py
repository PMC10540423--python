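"""Benchmark-adjusted Huff gravity model: utilities, shares, volumes.

The perceived utility of facility j for a decision-maker in area i is

    AA_ij = [ (1 - B_j) + BM * B_j * prod_f Á_f[j]^γ́_f ]
            * prod_f A_f[j]^γ_f * exp(-D_ij * DF)

where A_f are attraction variables observed for every facility (with
exponents γ_f), Á_f are attraction variables observed only for facilities
with availability flag B_j = 1 (with exponents γ́_f), D_ij is great-circle
distance in km and DF ≥ 0 the exponential decay rate. The benchmark
parameter BM ∈ (0, 1] scales down the utility of fully observed facilities
to level the playing field against facilities whose partial-variable
product is absent from the bracket.

Market shares follow the Huff rule: share_ij = AA_ij / Σ_j AA_ij, and
expected volumes are shares times the area market size V_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .region import FacilityAttraction, StudyRegion

__all__ = ["ModelParams", "PredictionMatrix", "utility_matrix",
           "market_shares", "expected_volumes", "predict"]


@dataclass
class ModelParams:
    """Parameters of the adjusted gravity model.

    Attributes
    ----------
    gamma : dict
        Exponent per complete attraction variable (e.g. ``{"beds": 0.92}``).
    gamma_partial : dict
        Exponent per partial attraction variable (e.g. ``{"reputation": 0.7}``,
        the reputation effect size).
    decay : float
        Distance-decay rate DF per km, ≥ 0.
    benchmark : float
        Benchmark parameter BM in (0, 1]; 1 when no correction applies.
    """

    gamma: dict[str, float] = field(default_factory=dict)
    gamma_partial: dict[str, float] = field(default_factory=dict)
    decay: float = 0.0
    benchmark: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.benchmark <= 1.0):
            raise ValueError("benchmark BM must lie in (0, 1]")
        if self.decay < 0.0:
            raise ValueError("decay DF must be non-negative")
        for d in (self.gamma, self.gamma_partial):
            for name, g in d.items():
                if not np.isfinite(g):
                    raise ValueError(f"exponent for {name!r} must be finite")

    def as_dict(self) -> dict[str, float]:
        out = {f"gamma_{k}": v for k, v in self.gamma.items()}
        out.update({f"gamma_{k}": v for k, v in self.gamma_partial.items()})
        out["decay"] = self.decay
        out["benchmark"] = self.benchmark
        return out


@dataclass
class PredictionMatrix:
    """Model-side quantities for one parameterization on one region."""

    numerators: np.ndarray        # AA_ij, I×J, strictly positive
    shares: np.ndarray            # row-stochastic I×J
    expected_volumes: np.ndarray  # I×J, rows sum to V_i
    facility_totals: np.ndarray   # length J


def _log_facility_utility(params: ModelParams, attraction: FacilityAttraction,
                          ) -> np.ndarray:
    """Log of the distance-free utility per facility (length J).

    Computed in log space so extreme exponents explored during annealing do
    not overflow. Partial-variable values where B_j = 0 never enter: the
    bracket reduces to 1 there regardless of any stored placeholder.
    """
    avail = attraction.availability
    n = attraction.n_facilities
    log_partial = np.zeros(n)
    for name, g in params.gamma_partial.items():
        if name not in attraction.partial:
            raise KeyError(f"partial variable {name!r} not present in attraction data")
        vals = attraction.partial[name]
        if np.any((avail == 1) & (~np.isfinite(vals) | (vals <= 0))):
            raise ValueError(f"partial variable {name!r} undefined where B_j = 1")
        log_partial = log_partial + g * np.log(np.where(avail == 1, vals, 1.0))
    # bracket: 1 where B=0, BM * prod(Á^γ́) where B=1
    log_bracket = np.where(
        avail == 1, np.log(params.benchmark) + log_partial, 0.0,
    )
    log_complete = np.zeros(n)
    for name, g in params.gamma.items():
        if name not in attraction.complete:
            raise KeyError(f"complete variable {name!r} not present in attraction data")
        log_complete = log_complete + g * np.log(attraction.complete[name])
    return log_bracket + log_complete


def log_utility_matrix(params: ModelParams, region: StudyRegion,
                       attraction: FacilityAttraction) -> np.ndarray:
    """Log-numerators log(AA_ij), shape I×J."""
    if attraction.n_facilities != region.n_facilities:
        raise ValueError("attraction tables and region disagree on J")
    return _log_facility_utility(params, attraction)[None, :] \
        - region.distances * params.decay


def utility_matrix(params: ModelParams, region: StudyRegion,
                   attraction: FacilityAttraction) -> np.ndarray:
    """Per-pair utilities AA_ij (the numerators of the model), shape I×J."""
    return np.exp(log_utility_matrix(params, region, attraction))


def market_shares(numerators: np.ndarray) -> np.ndarray:
    """Row-normalize utilities into choice probabilities."""
    numerators = np.asarray(numerators, dtype=float)
    if np.any(~np.isfinite(numerators)) or np.any(numerators <= 0):
        raise ValueError("numerators must be strictly positive and finite")
    row_sums = numerators.sum(axis=1, keepdims=True)
    return numerators / row_sums


def expected_volumes(shares: np.ndarray, market_sizes: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Expected volumes V_ij = share_ij * V_i and facility totals Σ_i V_ij."""
    shares = np.asarray(shares, dtype=float)
    if not np.allclose(shares.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("shares must be row-stochastic")
    vols = shares * np.asarray(market_sizes, dtype=float)[:, None]
    return vols, vols.sum(axis=0)


def predict(params: ModelParams, region: StudyRegion,
            attraction: FacilityAttraction) -> PredictionMatrix:
    """Full forward pass of the model, numerically stable in the shares.

    Shares are computed with a log-sum-exp normalization so that extreme
    parameter proposals (large exponents on large attraction values) cannot
    overflow, while the stored numerators remain the literal AA_ij.
    """
    log_aa = log_utility_matrix(params, region, attraction)
    log_shares = log_aa - logsumexp(log_aa, axis=1, keepdims=True)
    shares = np.exp(log_shares)
    vols = shares * np.asarray(region.market_sizes, dtype=float)[:, None]
    return PredictionMatrix(
        numerators=np.exp(log_aa),
        shares=shares,
        expected_volumes=vols,
        facility_totals=vols.sum(axis=0),
    )
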