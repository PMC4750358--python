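"""Per-study effect extraction.

Everything downstream pools log odds ratios, so this module is the single
place where a study row — either a 3x2 genotype table or a published
OR with 95% CI — becomes an :class:`EffectEstimate` (log-OR plus standard
error).  It also hosts the genetic-model collapse, the data-driven
dominant/recessive choice and the Hardy-Weinberg control filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

logger = logging.getLogger(__name__)

#: CI multiplier for 95% intervals.  Deliberately the conventional rounded
#: value rather than a re-derived quantile: published intervals round-trip
#: with 1.96.
Z95 = 1.96

RECESSIVE = "recessive"
DOMINANT = "dominant"
MODELS = (RECESSIVE, DOMINANT)


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio ``y`` with its standard error ``se``."""

    y: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise ValueError(f"non-finite log-OR for {self.label!r}: {self.y}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be finite and > 0, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.y)

    def ci(self, z: float = Z95) -> tuple[float, float]:
        """OR-scale Wald confidence interval."""
        return math.exp(self.y - z * self.se), math.exp(self.y + z * self.se)

    @property
    def variance(self) -> float:
        return self.se * self.se


@dataclass(frozen=True)
class ModelSelection:
    or1: EffectEstimate  # heterozygous vs wild-type homozygous
    or2: EffectEstimate  # mutant homozygous vs wild-type homozygous
    chosen: str
    rule: str = ""

    def __post_init__(self) -> None:
        if self.chosen not in MODELS:
            raise ValueError(f"chosen model must be one of {MODELS}")


@dataclass(frozen=True)
class HweResult:
    chi_square: float
    p_value: float
    excluded: bool
    alpha: float = field(default=0.01, compare=False)

    def __post_init__(self) -> None:
        if self.excluded != (self.p_value <= self.alpha):
            raise ValueError("excluded flag inconsistent with p_value <= alpha")


def odds_ratio_from_2x2(
    exposed_cases: float,
    unexposed_cases: float,
    exposed_controls: float,
    unexposed_controls: float,
    correction: float = 0.5,
    label: str = "",
) -> EffectEstimate:
    """Crude odds ratio of a 2x2 case-control table on the log scale.

    ``se = sqrt(1/a + 1/b + 1/c + 1/d)`` (Woolf).  When any cell is zero the
    Haldane-Anscombe ``correction`` is added to *all four* cells; otherwise
    the table is used as given.
    """
    cells = [exposed_cases, unexposed_cases, exposed_controls, unexposed_controls]
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if any(c == 0 for c in cells):
        if correction <= 0:
            raise ValueError("zero cell with no continuity correction: OR undefined")
        logger.info("zero cell in %r: adding %.3g to all cells", label, correction)
        cells = [c + correction for c in cells]
    a, b, c, d = cells
    if a * d == 0 or b * c == 0:
        raise ValueError(f"degenerate 2x2 table for {label!r}: OR undefined")
    y = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(y=y, se=se, label=label)


def collapse_genotypes(counts, model: str) -> tuple[int, int, int, int]:
    """Collapse a 3-genotype table into the 2x2 implied by ``model``.

    Returns ``(exposed_cases, unexposed_cases, exposed_controls,
    unexposed_controls)``.  Recessive: exposed = mutant homozygotes;
    dominant: exposed = carriers of at least one mutant allele.
    """
    if model == RECESSIVE:
        return (
            counts.cases_mtmt,
            counts.cases_wtwt + counts.cases_wtmt,
            counts.controls_mtmt,
            counts.controls_wtwt + counts.controls_wtmt,
        )
    if model == DOMINANT:
        return (
            counts.cases_wtmt + counts.cases_mtmt,
            counts.cases_wtwt,
            counts.controls_wtmt + counts.controls_mtmt,
            counts.controls_wtwt,
        )
    raise ValueError(f"unknown genetic model {model!r}")


def effect_from_reported(
    or_: float, lcl: float, ucl: float, label: str = ""
) -> EffectEstimate:
    """Recover (log-OR, SE) from a published OR and 95% CI.

    ``se = (ln ucl - ln lcl) / (2 * 1.96)`` — the standard back-calculation
    for Wald intervals on the log scale.
    """
    if not (or_ > 0 and lcl > 0 and ucl > 0):
        raise ValueError("OR and CI bounds must be positive")
    if not lcl < ucl:
        raise ValueError(f"CI bounds must satisfy lcl < ucl, got ({lcl}, {ucl})")
    se = (math.log(ucl) - math.log(lcl)) / (2 * Z95)
    return EffectEstimate(y=math.log(or_), se=se, label=label)


def effect_from_record(record, model: str | None = None) -> EffectEstimate:
    """Extract the effect for one study record.

    Genotype counts take precedence (collapsed under ``model``, defaulting
    to the record's own ``reported_model``); otherwise the published OR/CI
    is back-transformed.
    """
    model = model or record.reported_model
    label = record.label
    if record.genotype_counts is not None:
        if model not in MODELS:
            raise ValueError(f"cannot collapse genotypes for {label!r} under model {model!r}")
        table = collapse_genotypes(record.genotype_counts, model)
        return odds_ratio_from_2x2(*table, label=label)
    if record.reported_or is None:
        raise ValueError(f"record {label!r} carries neither genotype counts nor a reported OR")
    return effect_from_reported(
        record.reported_or, record.reported_lcl, record.reported_ucl, label=label
    )


def _significant(est: EffectEstimate, z: float = Z95) -> bool:
    lo, hi = est.ci(z)
    return lo > 1.0 or hi < 1.0


def select_genetic_model(or1: EffectEstimate, or2: EffectEstimate) -> ModelSelection:
    """Choose between recessive and dominant inheritance.

    Decision rules, with "different from 1" read as the 95% CI excluding 1:

    * OR2 significant, OR1 not  -> recessive
    * both significant          -> dominant
    * neither significant       -> tie-break on effect magnitude:
      recessive iff ``|y2| >= |y1|``, else dominant.
    """
    sig1, sig2 = _significant(or1), _significant(or2)
    if sig2 and not sig1:
        chosen, rule = RECESSIVE, "or2 != 1 and or1 = 1"
    elif sig1 and sig2:
        chosen, rule = DOMINANT, "or1 = or2 != 1"
    else:
        chosen = RECESSIVE if abs(or2.y) >= abs(or1.y) else DOMINANT
        rule = "tie-break on |log-OR|"
    logger.info("model selection: %s (%s)", chosen, rule)
    return ModelSelection(or1=or1, or2=or2, chosen=chosen, rule=rule)


def hwe_test(
    controls_wtwt: int,
    controls_wtmt: int,
    controls_mtmt: int,
    alpha: float = 0.01,
    exact: bool = False,
) -> HweResult:
    """Hardy-Weinberg test on control genotypes.

    Default is the 1-df Pearson chi-square against (p^2, 2pq, q^2) at the
    observed allele frequency; ``exact=True`` switches to the conditional
    exact test (sum of heterozygote-count probabilities no larger than the
    observed one).  ``excluded`` is True when ``p <= alpha`` — the boundary
    counts as exclusion.
    """
    obs = (controls_wtwt, controls_wtmt, controls_mtmt)
    if any(o < 0 for o in obs):
        raise ValueError("genotype counts must be non-negative")
    n = sum(obs)
    if n < 1:
        raise ValueError("need at least one control genotype")
    n_mut = controls_wtmt + 2 * controls_mtmt
    q = n_mut / (2 * n)
    if q in (0.0, 1.0):
        logger.info("monomorphic controls: HWE chi-square set to 0, p = 1")
        return HweResult(chi_square=0.0, p_value=1.0, excluded=False, alpha=alpha)
    if exact:
        p = _hwe_exact_p(n, n_mut, controls_wtmt)
        chi2 = _hwe_chi2(obs, n, q)
    else:
        chi2 = _hwe_chi2(obs, n, q)
        p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi_square=chi2, p_value=p, excluded=p <= alpha, alpha=alpha)


def _hwe_chi2(obs: tuple[int, int, int], n: int, q: float) -> float:
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    return sum((o - e) ** 2 / e for o, e in zip(obs, expected))


def _hwe_exact_p(n: int, n_mut: int, het_obs: int) -> float:
    """Conditional exact HWE p-value (sum over heterozygote counts)."""
    n_wild = 2 * n - n_mut
    rare = min(n_mut, n_wild)
    het_min = rare % 2

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + math.lgamma(n_mut + 1)
            + math.lgamma(n_wild + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(het_min, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    m = max(logs.values())
    total = sum(math.exp(v - m) for v in logs.values())
    obs_p = math.exp(logs[het_obs if het_obs in logs else het_min] - m)
    acc = sum(
        math.exp(v - m) for v in logs.values() if math.exp(v - m) <= obs_p * (1 + 1e-12)
    )
    return min(1.0, acc / total)
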