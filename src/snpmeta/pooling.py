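"""Fixed-effect and DerSimonian-Laird random-effects pooling.

Also: Cochran's Q, I-squared, per-stratum subgroup pooling, leave-one-out
sensitivity re-pooling and Galbraith (radial) outlier detection.  All
arithmetic is on the log-OR scale; odds ratios appear only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import Z95, EffectEstimate

FACTORS = ("design", "ethnicity", "sample_size", "tumour_site")

#: Galbraith band: points with |standardized residual| above this contribute
#: disproportionately to Q.
GALBRAITH_THRESHOLD = 2.0


@dataclass(frozen=True)
class PooledResult:
    k: int
    y: float              # pooled log-OR
    se: float
    q: float
    df: int
    p_heterogeneity: float
    tau2: float
    i2: float             # percent in [0, 100]
    weights: tuple[float, ...]
    labels: tuple[str, ...]
    method: str = "random"

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not 0 <= self.i2 <= 100:
            raise ValueError("i2 must lie in [0, 100]")
        if self.df != self.k - 1:
            raise ValueError("df must equal k - 1")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.y)

    @property
    def ci(self) -> tuple[float, float]:
        return math.exp(self.y - Z95 * self.se), math.exp(self.y + Z95 * self.se)

    @property
    def degenerate(self) -> bool:
        """Single-study 'pool': reported, but not a synthesis."""
        return self.k == 1


@dataclass(frozen=True)
class GalbraithPoint:
    label: str
    precision: float            # 1 / se
    standardized_effect: float  # y / se
    residual: float             # standardized deviation from the pooled line
    outlier: bool


def _arrays(estimates: list[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if not estimates:
        raise ValueError("cannot pool an empty collection")
    y = np.array([e.y for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    return y, se


def fixed_effect_pool(estimates: list[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pool (the internal step of DL)."""
    y, se = _arrays(estimates)
    w = 1.0 / se**2
    y_pooled = float(np.sum(w * y) / np.sum(w))
    se_pooled = float(1.0 / math.sqrt(np.sum(w)))
    q, df, p = _q_stats(y, w, y_pooled)
    return PooledResult(
        k=len(estimates), y=y_pooled, se=se_pooled,
        q=q, df=df, p_heterogeneity=p, tau2=0.0, i2=i_squared(q, df),
        weights=tuple(w), labels=tuple(e.label for e in estimates),
        method="fixed",
    )


def _q_stats(y: np.ndarray, w: np.ndarray, y_fixed: float) -> tuple[float, int, float]:
    df = len(y) - 1
    if df < 1:
        return 0.0, 0, 1.0
    q = float(np.sum(w * (y - y_fixed) ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def cochran_q(
    estimates: list[EffectEstimate], y_pooled_fixed: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q with fixed-effect weights; chi-square p on k-1 df."""
    if len(estimates) < 2:
        raise ValueError("Q requires at least two estimates")
    y, se = _arrays(estimates)
    w = 1.0 / se**2
    if y_pooled_fixed is None:
        y_pooled_fixed = float(np.sum(w * y) / np.sum(w))
    return _q_stats(y, w, y_pooled_fixed)


def i_squared(q: float, df: int) -> float:
    """Heterogeneity percentage ``max(0, (Q - df) / Q) * 100``; 0 when Q = 0."""
    if q <= 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def dl_tau2(estimates: list[EffectEstimate], q: float | None = None) -> float:
    """DerSimonian-Laird moment estimator ``max(0, (Q - df) / C)``."""
    if len(estimates) < 2:
        raise ValueError("tau2 estimation requires at least two estimates")
    y, se = _arrays(estimates)
    w = 1.0 / se**2
    if q is None:
        q, _, _ = cochran_q(estimates)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    df = len(estimates) - 1
    return max(0.0, (q - df) / c)


def random_effects_pool(estimates: list[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pool.

    ``k = 1`` degenerates to the single estimate (flagged via
    :attr:`PooledResult.degenerate`).
    """
    y, se = _arrays(estimates)
    if len(estimates) == 1:
        return PooledResult(
            k=1, y=float(y[0]), se=float(se[0]), q=0.0, df=0,
            p_heterogeneity=1.0, tau2=0.0, i2=0.0,
            weights=(float(1.0 / se[0] ** 2),),
            labels=(estimates[0].label,), method="random",
        )
    w = 1.0 / se**2
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q, df, p = _q_stats(y, w, y_fixed)
    tau2 = dl_tau2(estimates, q=q)
    w_star = 1.0 / (se**2 + tau2)
    y_pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se_pooled = float(1.0 / math.sqrt(np.sum(w_star)))
    return PooledResult(
        k=len(estimates), y=y_pooled, se=se_pooled,
        q=q, df=df, p_heterogeneity=p, tau2=tau2, i2=i_squared(q, df),
        weights=tuple(w_star), labels=tuple(e.label for e in estimates),
        method="random",
    )


def pool(estimates: list[EffectEstimate], method: str = "random") -> PooledResult:
    if method == "random":
        return random_effects_pool(estimates)
    if method == "fixed":
        return fixed_effect_pool(estimates)
    raise ValueError(f"unknown pooling method {method!r}")


def leave_one_out(
    estimates: list[EffectEstimate],
) -> list[tuple[str, PooledResult]]:
    """Re-pool after omitting each unit in turn (tau2 re-estimated each time)."""
    if len(estimates) < 3:
        raise ValueError("leave-one-out requires at least three estimates")
    out = []
    for i, est in enumerate(estimates):
        rest = estimates[:i] + estimates[i + 1:]
        out.append((est.label, random_effects_pool(rest)))
    return out


def galbraith(
    estimates: list[EffectEstimate],
    threshold: float = GALBRAITH_THRESHOLD,
) -> list[GalbraithPoint]:
    """Radial-plot residuals against the fixed-effect pooled line.

    The no-intercept regression of ``y/se`` on ``1/se`` has slope equal to
    the fixed-effect pooled log-OR, so each residual is
    ``(y_i - y_fixed) / se_i``; units beyond ``threshold`` in absolute value
    are the disproportionate contributors to Q.
    """
    if len(estimates) < 3:
        raise ValueError("Galbraith analysis requires at least three estimates")
    fixed = fixed_effect_pool(estimates)
    points = []
    for est in estimates:
        residual = (est.y - fixed.y) / est.se
        points.append(
            GalbraithPoint(
                label=est.label,
                precision=1.0 / est.se,
                standardized_effect=est.y / est.se,
                residual=residual,
                outlier=abs(residual) > threshold,
            )
        )
    return points


def subgroup_analysis(
    records: list,
    factor: str,
    snp_id: str | None = None,
    model: str | None = None,
) -> dict[str, PooledResult]:
    """Pool each level of a stratification factor independently.

    tau2 is re-estimated within every stratum.  Tumour-site stratification
    keeps shared-control rows separate (each row *is* its site); all other
    factors aggregate them first.
    """
    from .study_io import build_analysis_units, classify_sample_size

    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if snp_id is not None:
        records = [r for r in records if r.snp_id == snp_id]
    if len({r.snp_id for r in records}) > 1:
        raise ValueError("subgroup analysis requires records filtered to one SNP")

    def level_of(rec) -> str:
        if factor == "sample_size":
            return classify_sample_size(rec)
        return getattr(rec, "tumour_site" if factor == "tumour_site" else factor)

    levels: dict[str, list] = {}
    for rec in records:
        levels.setdefault(level_of(rec), []).append(rec)

    out: dict[str, PooledResult] = {}
    for level, members in levels.items():
        units = build_analysis_units(
            members, model=model, aggregate=(factor != "tumour_site")
        )
        out[level] = random_effects_pool([u.effect for u in units])
    return out


def results_table(pooled: dict[str, PooledResult], snp_id: str = "") -> pd.DataFrame:
    """Report-style table: one row per stratum, ORs at 2 decimals, I2 at 1."""
    rows = []
    for stratum, res in pooled.items():
        lo, hi = res.ci
        rows.append({
            "snp_id": snp_id,
            "stratum": stratum,
            "k": res.k,
            "or": round(res.odds_ratio, 2),
            "ci_low": round(lo, 2),
            "ci_high": round(hi, 2),
            "i2_pct": round(res.i2, 1),
            "p_heterogeneity": res.p_heterogeneity,
            "tau2": res.tau2,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows)


def forest_data(
    estimates: list[EffectEstimate], pooled: PooledResult
) -> pd.DataFrame:
    """Per-study OR, CI and percent weight plus the pooled summary row."""
    total_w = sum(pooled.weights)
    rows = []
    for est, w in zip(estimates, pooled.weights):
        lo, hi = est.ci()
        rows.append({
            "label": est.label, "or": est.odds_ratio,
            "ci_low": lo, "ci_high": hi,
            "weight_pct": 100.0 * w / total_w, "pooled": False,
        })
    lo, hi = pooled.ci
    rows.append({
        "label": f"Overall ({pooled.method} effects)", "or": pooled.odds_ratio,
        "ci_low": lo, "ci_high": hi, "weight_pct": 100.0, "pooled": True,
    })
    return pd.DataFrame(rows)
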