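"""Publication-bias diagnostics: Egger regression, Begg rank correlation,
funnel-plot data export.

Both tests are descriptive here — they never gate a pooling decision.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import Z95, EffectEstimate
from .pooling import PooledResult, fixed_effect_pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasTestResult:
    method: str         # "egger" | "begg"
    statistic: float    # Egger intercept, or Kendall's tau
    dispersion: float   # SE of the intercept (Egger) / null variance of tau (Begg)
    p_value: float
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.method == "begg" and not -1 <= self.statistic <= 1:
            raise ValueError("Kendall's tau outside [-1, 1]")


def egger_test(
    estimates: list[EffectEstimate], weighted: bool = False
) -> BiasTestResult:
    """Egger's regression asymmetry test.

    Default (classic) form: OLS of the standardized effect ``y/se`` on the
    precision ``1/se``; the intercept is the asymmetry statistic, tested
    two-sided against t with k-2 df.  ``weighted=True`` runs the equivalent
    WLS of ``y`` on ``se`` with weights ``1/se^2`` (same point estimate,
    kept for cross-checking against other software).
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger's test requires at least three estimates")
    y = np.array([e.y for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.ptp(se) == 0 and np.ptp(y) == 0:
        # identical studies: flat funnel, no asymmetry by construction
        return BiasTestResult("egger", 0.0, float("nan"), 1.0, k)
    if np.ptp(se) == 0:
        raise ValueError("degenerate regressor: all precisions identical")
    if weighted:
        exog = sm.add_constant(se)
        fit = sm.WLS(y, exog, weights=1.0 / se**2).fit()
        intercept_idx = 1  # slope on se plays the intercept role in this form
        intercept = fit.params[intercept_idx]
        stderr = fit.bse[intercept_idx]
    else:
        exog = sm.add_constant(1.0 / se)
        fit = sm.OLS(y / se, exog).fit()
        intercept = fit.params[0]
        stderr = fit.bse[0]
    t = intercept / stderr
    p = 2.0 * float(stats.t.sf(abs(t), df=k - 2))
    return BiasTestResult("egger", float(intercept), float(stderr), p, k)


def _kendall_counts(u, v) -> tuple[int, int, int]:
    """Concordant pairs, discordant pairs, and usable (untied-in-both) pairs."""
    conc = disc = usable = 0
    u = list(u)
    v = list(v)
    for i, j in itertools.combinations(range(len(u)), 2):
        du = u[j] - u[i]
        dv = v[j] - v[i]
        s = du * dv
        if s > 0:
            conc += 1
        elif s < 0:
            disc += 1
        if du != 0 and dv != 0:
            usable += 1
    return conc, disc, usable


def begg_test(
    estimates: list[EffectEstimate],
    continuity: bool = True,
    exact: bool = False,
) -> BiasTestResult:
    """Begg-Mazumdar rank correlation test.

    Correlates the variance-stabilized deviates
    ``v_i = (y_i - y_fixed) / sqrt(se_i^2 - se_fixed^2)`` with the study
    variances ``se_i^2`` via Kendall's tau.  The default p-value is the
    tie-corrected normal approximation of ``P - Q`` with a continuity
    correction; ``exact=True`` enumerates all rank permutations instead
    (intended for k <= 8; cost grows as k!).
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Begg's test requires at least three estimates")
    fixed = fixed_effect_pool(estimates)
    se = np.array([e.se for e in estimates])
    y = np.array([e.y for e in estimates])
    var = se**2
    if np.ptp(var) == 0:
        logger.info("all study variances equal: Begg's tau undefined, p = 1")
        return BiasTestResult("begg", 0.0, float("nan"), 1.0, k)
    stabilized = var - fixed.se**2
    deviates = (y - fixed.y) / np.sqrt(stabilized)

    conc, disc, _ = _kendall_counts(deviates, var)
    n_pairs = k * (k - 1) // 2
    # tau-a against all pairs; ties only arise from tied variances
    tau = (conc - disc) / n_pairs

    if exact:
        p = _exact_begg_p(deviates, var, conc - disc)
        null_var = _begg_null_variance(deviates, var, k)
        return BiasTestResult("begg", float(tau), null_var, p, k)

    null_var = _begg_null_variance(deviates, var, k)
    score = conc - disc
    if continuity:
        score = max(0.0, abs(score) - 1.0)
    else:
        score = abs(score)
    z = score / math.sqrt(null_var) if null_var > 0 else 0.0
    p = 2.0 * float(stats.norm.sf(z))
    return BiasTestResult("begg", float(tau), null_var, min(1.0, p), k)


def _tie_term(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float(sum(t * (t - 1) * (2 * t + 5) for t in counts))


def _begg_null_variance(u: np.ndarray, v: np.ndarray, k: int) -> float:
    """Null variance of P - Q with the standard tie correction."""
    base = k * (k - 1) * (2 * k + 5)
    return (base - _tie_term(u) - _tie_term(v)) / 18.0


def _exact_begg_p(u: np.ndarray, v: np.ndarray, observed_score: int) -> float:
    """Permutation distribution of P - Q over all orderings of one margin."""
    order = np.argsort(v)
    v_sorted = v[order]
    at_least = total = 0
    for perm in itertools.permutations(u):
        conc, disc, _ = _kendall_counts(np.array(perm), v_sorted)
        total += 1
        if abs(conc - disc) >= abs(observed_score):
            at_least += 1
    return at_least / total


def funnel_data(
    estimates: list[EffectEstimate], pooled: PooledResult
) -> pd.DataFrame:
    """Per-study funnel coordinates plus pseudo-95% funnel boundaries.

    Columns: label, or, se, precision, plus (constant per table) the pooled
    OR reference line and the OR-scale boundaries ``exp(y_pooled +/- 1.96 se)``
    evaluated at each study's se.
    """
    rows = []
    for est in estimates:
        rows.append({
            "label": est.label,
            "or": est.odds_ratio,
            "se": est.se,
            "precision": 1.0 / est.se,
            "pooled_or": pooled.odds_ratio,
            "funnel_low": math.exp(pooled.y - Z95 * est.se),
            "funnel_high": math.exp(pooled.y + Z95 * est.se),
        })
    return pd.DataFrame(rows)
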