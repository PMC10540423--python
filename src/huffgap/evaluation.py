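"""Accuracy metrics and diagnostics for fitted gravity models.

Facility-level MAPE, split by whether a facility belongs to the in-group
(partial variable observed, B_j = 1) or the out-group (B_j = 0); the
Breusch-Pagan heteroskedasticity test of effect-size estimation errors
against data availability; and one-sided Student-t upper confidence bounds
over replicate runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

logger = logging.getLogger(__name__)

__all__ = ["GroupedAccuracy", "mape", "grouped_accuracy",
           "breusch_pagan_vs_p", "one_sided_upper_bound"]


@dataclass
class GroupedAccuracy:
    """Facility-level MAPE (%) split by availability group.

    ``mape_in`` / ``mape_out`` are ``None`` when the corresponding group is
    empty (availability fractions of 0 or 1).
    """

    mape_in: float | None
    mape_out: float | None
    mape_all: float
    n_in: int
    n_out: int


def mape(observed: np.ndarray, estimated: np.ndarray,
         mask: np.ndarray | None = None) -> float:
    """Mean absolute percentage error, in percent, over an optional subset.

    Facilities with zero observed volume carry an undefined percentage error
    and are excluded (with a warning); an empty evaluation set is an error.
    """
    observed = np.asarray(observed, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if observed.shape != estimated.shape:
        raise ValueError("observed and estimated must have equal length")
    if mask is not None:
        sel = np.asarray(mask)
        if sel.dtype != bool:
            sel = sel.astype(bool)
        observed, estimated = observed[sel], estimated[sel]
    if observed.size == 0:
        raise ValueError("cannot compute MAPE over an empty subset")
    nonzero = observed > 0
    if not nonzero.all():
        logger.warning("excluding %d facilities with zero observed volume from MAPE",
                       int((~nonzero).sum()))
        observed, estimated = observed[nonzero], estimated[nonzero]
        if observed.size == 0:
            raise ValueError("all observed values are zero; MAPE undefined")
    return float(100.0 * np.mean(np.abs(observed - estimated) / observed))


def grouped_accuracy(observed_totals: np.ndarray, estimated_totals: np.ndarray,
                     availability: np.ndarray) -> GroupedAccuracy:
    """MAPE per availability group plus overall."""
    avail = np.asarray(availability).astype(bool)
    n_in = int(avail.sum())
    n_out = int((~avail).sum())
    return GroupedAccuracy(
        mape_in=mape(observed_totals, estimated_totals, avail) if n_in else None,
        mape_out=mape(observed_totals, estimated_totals, ~avail) if n_out else None,
        mape_all=mape(observed_totals, estimated_totals),
        n_in=n_in, n_out=n_out,
    )


def breusch_pagan_vs_p(estimate_errors: np.ndarray, p_values: np.ndarray,
                       ) -> tuple[float, float]:
    """Breusch-Pagan test of error variance as a function of availability p.

    Regresses the squared estimation errors on p (auxiliary regression with
    intercept) and returns the F statistic of that regression together with
    its p-value. A small p-value indicates the spread of the effect-size
    estimates changes systematically with data availability.
    """
    errors = np.asarray(estimate_errors, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if errors.shape != p.shape or errors.ndim != 1:
        raise ValueError("errors and p must be equal-length 1-d vectors")
    if np.unique(p).size < 3:
        raise ValueError("need at least 3 distinct availability values")
    exog = sm.add_constant(p)
    _lm, _lm_pvalue, fvalue, f_pvalue = het_breuschpagan(errors, exog)
    return float(fvalue), float(f_pvalue)


def one_sided_upper_bound(replicate_values: np.ndarray,
                          confidence: float = 0.05) -> float:
    """Right-tailed (1 - confidence) upper bound on the mean of replicates.

    mean + t_{1-confidence, n-1} * sd / sqrt(n), with the sample standard
    deviation (ddof=1). At n = 5 and the 5% level the critical value is
    t_{0.95, 4} ≈ 2.13.
    """
    x = np.asarray(replicate_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 replicates")
    n = x.size
    t_crit = stats.t.ppf(1.0 - confidence, df=n - 1)
    return float(x.mean() + t_crit * x.std(ddof=1) / np.sqrt(n))
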