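"""Synthetic case-control genotype studies.

Controls are drawn multinomially under Hardy-Weinberg proportions at a
configurable mutant-allele frequency; cases tilt the exposed genotype
class's odds by a per-study OR drawn around the true OR with between-study
variance tau2.  Optional censoring of non-significant studies emulates
publication bias.  Every draw is a pure function of the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import effects
from .effects import DOMINANT, RECESSIVE, EffectEstimate
from .study_io import GenotypeCounts, StudyRecord

logger = logging.getLogger(__name__)

# per-study size distribution when n_cases is not pinned: log-uniform cases
# in [100, 2000], controls = cases * U(0.8, 1.5)
_CASE_RANGE = (100, 2000)
_CONTROL_RATIO = (0.8, 1.5)


@dataclass(frozen=True)
class SimulationConfig:
    allele_freq: float          # mutant-allele frequency in controls
    true_or: float = 1.0        # OR of the exposed genotype class
    model: str = RECESSIVE
    n_cases: int | None = None  # None -> drawn per study
    n_controls: int | None = None
    tau2: float = 0.0
    k_studies: int = 1
    bias_severity: float = 0.0  # censoring prob. for non-significant studies
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.model not in (RECESSIVE, DOMINANT):
            raise ValueError(f"unknown model {self.model!r}")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.k_studies < 1:
            raise ValueError("k_studies must be positive")
        if not 0 <= self.bias_severity <= 1:
            raise ValueError("bias_severity must lie in [0, 1]")


def control_genotype_probs(allele_freq: float) -> np.ndarray:
    """HWE genotype probabilities (wtwt, wtmt, mtmt) for mutant frequency q."""
    q = allele_freq
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def case_genotype_probs(
    allele_freq: float, study_or: float, model: str
) -> np.ndarray:
    """Case genotype probabilities: exposed-class odds tilted by ``study_or``.

    The collapsed 2x2 of the resulting population has odds ratio exactly
    ``study_or`` under the configured model.
    """
    probs = control_genotype_probs(allele_freq).copy()
    exposed = np.array([False, False, True]) if model == RECESSIVE else np.array(
        [False, True, True]
    )
    probs[exposed] *= study_or
    return probs / probs.sum()


def simulate_study(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    index: int = 0,
) -> StudyRecord:
    """Draw one case-control study with full genotype counts.

    The realised per-study log-OR travels in ``true_log_or`` (hidden from
    the public CSV schema unless exported explicitly).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cases, n_controls = _draw_sizes(config, rng)
    study_log_or = math.log(config.true_or) + (
        rng.normal(0.0, math.sqrt(config.tau2)) if config.tau2 > 0 else 0.0
    )
    control_p = control_genotype_probs(config.allele_freq)
    case_p = case_genotype_probs(
        config.allele_freq, math.exp(study_log_or), config.model
    )
    if (n_controls * control_p).min() < 1 or (n_cases * case_p).min() < 1:
        logger.warning(
            "study %d: expected genotype cell below 1 (n=%d/%d, q=%.3g)",
            index, n_cases, n_controls, config.allele_freq,
        )
    controls = rng.multinomial(n_controls, control_p)
    cases = rng.multinomial(n_cases, case_p)
    counts = GenotypeCounts(
        cases_wtwt=int(cases[0]), cases_wtmt=int(cases[1]), cases_mtmt=int(cases[2]),
        controls_wtwt=int(controls[0]), controls_wtmt=int(controls[1]),
        controls_mtmt=int(controls[2]),
    )
    return StudyRecord(
        snp_id="rs0",
        author=f"Synthetic {index:03d}",
        year=2020,
        tumour_site="lung",
        country="Simulated",
        ethnicity="Mixed",
        design="population",
        n_cases=n_cases,
        n_controls=n_controls,
        genotype_counts=counts,
        reported_model=config.model,
        true_log_or=study_log_or,
    )


def _draw_sizes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    if config.n_cases is not None:
        n_cases = config.n_cases
        n_controls = (
            config.n_controls if config.n_controls is not None else config.n_cases
        )
        return n_cases, n_controls
    lo, hi = _CASE_RANGE
    n_cases = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    n_controls = int(round(n_cases * rng.uniform(*_CONTROL_RATIO)))
    return n_cases, n_controls


def simulate_collection(config: SimulationConfig) -> list[StudyRecord]:
    """Independent studies; censoring applied after the fact.

    With ``bias_severity > 0`` a study whose collapsed-OR 95% CI contains 1
    is dropped with that probability.
    """
    rng = np.random.default_rng(config.seed)
    records: list[StudyRecord] = []
    for i in range(config.k_studies):
        rec = simulate_study(config, rng=rng, index=i)
        if config.bias_severity > 0:
            est = effects.effect_from_record(rec)
            lo, hi = est.ci()
            non_significant = lo <= 1.0 <= hi
            if non_significant and rng.uniform() < config.bias_severity:
                continue
        records.append(rec)
    return records


def simulate_effects(
    k: int,
    mu: float = 0.0,
    tau2: float = 0.0,
    se_range: tuple[float, float] = (0.1, 0.5),
    rng: np.random.Generator | int | None = None,
) -> list[EffectEstimate]:
    """Estimate-level generator for calibration studies.

    Draws ``se_i ~ U(se_range)`` and ``y_i ~ N(mu, tau2 + se_i^2)`` — a
    symmetric null (no small-study effect) whenever mu and tau2 are fixed.
    Much faster than full genotype simulation, for type-I-error sweeps.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    se = rng.uniform(*se_range, size=k)
    y = rng.normal(mu, np.sqrt(tau2 + se**2))
    return [
        EffectEstimate(y=float(yi), se=float(si), label=f"sim{i:03d}")
        for i, (yi, si) in enumerate(zip(y, se))
    ]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
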