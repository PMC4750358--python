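"""End-to-end analysis orchestration.

Order of operations: read -> validate -> HWE filter -> effect extraction
(per-SNP model assignment or override) -> shared-control aggregation ->
overall pool -> stratum pools -> bias tests -> Galbraith -> leave-one-out.
The bundle is a plain dict (JSON-serialisable) plus tabular exports; the
whole pipeline is a pure function of (input file, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bias, effects, pooling, study_io
from .pooling import FACTORS

logger = logging.getLogger(__name__)

#: Genetic model used for each SNP of the packaged reference table.  The
#: recessive assignments are data-driven (the dominant/recessive selection
#: rule applied to the crude OR1/OR2); the dominant ones are forced by the
#: source studies reporting carrier counts only.
DEFAULT_MODELS = {
    "rs762551": "recessive",
    "rs2470890": "recessive",
    "rs2472304": "recessive",
    "rs2069514": "dominant",
    "rs2069526": "dominant",
    "rs35694136": "dominant",
}


@dataclass(frozen=True)
class AnalysisConfig:
    input_path: str | Path | None = None  # None -> packaged fixture
    snp: str | None = None
    model_override: dict[str, str] = field(default_factory=dict)
    hwe_alpha: float = 0.01
    strata: tuple[str, ...] = FACTORS
    run_bias_tests: bool = True
    run_loo: bool = True
    run_galbraith: bool = True
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must lie in (0, 1)")
        unknown = set(self.strata) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}; supported: {FACTORS}")


def _pooled_dict(res: pooling.PooledResult) -> dict:
    lo, hi = res.ci
    return {
        "k": res.k,
        "or": res.odds_ratio,
        "or_2dp": round(res.odds_ratio, 2),
        "ci_low": lo,
        "ci_high": hi,
        "ci_2dp": [round(lo, 2), round(hi, 2)],
        "log_or": res.y,
        "se": res.se,
        "q": res.q,
        "df": res.df,
        "p_heterogeneity": res.p_heterogeneity,
        "tau2": res.tau2,
        "i2_pct": res.i2,
        "degenerate": res.degenerate,
    }


def _hwe_filter(records: list, alpha: float) -> tuple[list, list[dict]]:
    kept, excluded = [], []
    for rec in records:
        gc = rec.genotype_counts
        if gc is None:
            kept.append(rec)
            continue
        res = effects.hwe_test(
            gc.controls_wtwt, gc.controls_wtmt, gc.controls_mtmt, alpha=alpha
        )
        if res.excluded:
            excluded.append({
                "label": rec.label, "reason": "HWE deviation in controls",
                "hwe_p": res.p_value, "hwe_chi2": res.chi_square,
            })
        else:
            kept.append(rec)
    return kept, excluded


def analyze_snp(
    records: list,
    snp_id: str,
    config: AnalysisConfig,
) -> dict:
    """Full analysis bundle for the records of one SNP (already HWE-filtered)."""
    model = config.model_override.get(snp_id) or DEFAULT_MODELS.get(snp_id)
    units = study_io.build_analysis_units(records, model=model, aggregate=True)
    ests = [u.effect for u in units]
    overall = pooling.random_effects_pool(ests)

    bundle: dict = {
        "snp_id": snp_id,
        "model": model,
        "n_records": len(records),
        "n_units": len(units),
        "aggregated_units": [
            {"label": u.label, "members": [r.label for r in u.records]}
            for u in units if u.is_aggregate
        ],
        "overall": _pooled_dict(overall),
        "strata": {},
    }

    for factor in config.strata:
        by_level = pooling.subgroup_analysis(records, factor, model=model)
        bundle["strata"][factor] = {
            level: _pooled_dict(res) for level, res in sorted(by_level.items())
        }

    if config.run_bias_tests and len(ests) >= 3:
        egger = bias.egger_test(ests)
        begg = bias.begg_test(ests)
        bundle["bias_tests"] = {
            "egger": {"intercept": egger.statistic, "se": egger.dispersion,
                      "p": egger.p_value, "k": egger.k},
            "begg": {"tau": begg.statistic, "null_variance": begg.dispersion,
                     "p": begg.p_value, "k": begg.k},
        }

    if config.run_galbraith and len(ests) >= 3:
        points = pooling.galbraith(ests)
        bundle["galbraith"] = [dataclasses.asdict(p) for p in points]
        bundle["galbraith_outliers"] = [p.label for p in points if p.outlier]

    if config.run_loo and len(ests) >= 3:
        bundle["leave_one_out"] = [
            {"omitted": label, **_pooled_dict(res)}
            for label, res in pooling.leave_one_out(ests)
        ]

    bundle["_units"] = units  # stripped before serialisation
    bundle["_overall"] = overall
    return bundle


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the pipeline for every SNP selected by the config."""
    if config.input_path is None:
        records = study_io.load_fixture()
    else:
        records = study_io.read_study_table(config.input_path)
    if config.snp is not None:
        records = [r for r in records if r.snp_id == config.snp]
        if not records:
            raise ValueError(f"no records for SNP {config.snp!r}")
    unknown = set(config.model_override) - {r.snp_id for r in records}
    if unknown:
        raise ValueError(f"model override names unknown SNPs: {sorted(unknown)}")

    records, excluded = _hwe_filter(records, config.hwe_alpha)
    if not records:
        raise ValueError("no records left after HWE filtering")

    snps: dict[str, list] = {}
    for rec in records:
        snps.setdefault(rec.snp_id, []).append(rec)

    report = {
        "config": {
            "snp": config.snp,
            "hwe_alpha": config.hwe_alpha,
            "strata": list(config.strata),
            "model_override": dict(config.model_override),
        },
        "hwe_exclusions": excluded,
        "analyses": {snp: analyze_snp(recs, snp, config) for snp, recs in snps.items()},
    }
    if config.out_dir is not None:
        _write_bundle(report, Path(config.out_dir))
    return report


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items() if not k.startswith("_")}
    if isinstance(obj, list):
        return [_strip_private(v) for v in obj]
    return obj


def _write_bundle(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(_strip_private(report), fh, indent=2, sort_keys=True)
        fh.write("\n")

    tables, loo_rows, bias_rows = [], [], []
    for snp, bundle in report["analyses"].items():
        overall = {"overall": bundle["_overall"]}
        tables.append(pooling.results_table(overall, snp_id=snp))
        for factor, levels in bundle["strata"].items():
            rows = pd.DataFrame([
                {"snp_id": snp, "stratum": f"{factor}:{level}",
                 "k": d["k"], "or": d["or_2dp"],
                 "ci_low": d["ci_2dp"][0], "ci_high": d["ci_2dp"][1],
                 "i2_pct": round(d["i2_pct"], 1),
                 "p_heterogeneity": d["p_heterogeneity"],
                 "tau2": d["tau2"], "degenerate": d["degenerate"]}
                for level, d in levels.items()
            ])
            tables.append(rows)
        units = bundle["_units"]
        ests = [u.effect for u in units]
        pooled = bundle["_overall"]
        pooling.forest_data(ests, pooled).to_csv(
            out_dir / f"forest_{snp}.csv", index=False
        )
        bias.funnel_data(ests, pooled).to_csv(
            out_dir / f"funnel_{snp}.csv", index=False
        )
        if "galbraith" in bundle:
            pd.DataFrame(bundle["galbraith"]).to_csv(
                out_dir / f"galbraith_{snp}.csv", index=False
            )
        for row in bundle.get("leave_one_out", []):
            loo_rows.append({"snp_id": snp, **{k: v for k, v in row.items()
                                               if k in ("omitted", "or_2dp", "ci_2dp", "i2_pct")}})
        if "bias_tests" in bundle:
            for method, vals in bundle["bias_tests"].items():
                bias_rows.append({"snp_id": snp, "method": method, **vals})

    pd.concat(tables, ignore_index=True).to_csv(
        out_dir / "results.tsv", sep="\t", index=False
    )
    if loo_rows:
        pd.DataFrame(loo_rows).to_csv(out_dir / "leave_one_out.csv", index=False)
    if bias_rows:
        pd.DataFrame(bias_rows).to_csv(out_dir / "bias_tests.tsv", sep="\t", index=False)
    with (out_dir / "exclusions.log").open("w", encoding="utf-8") as fh:
        for entry in report["hwe_exclusions"]:
            fh.write(f"{entry['label']}\t{entry['reason']}\tp={entry['hwe_p']:.4g}\n")
        for snp, bundle in report["analyses"].items():
            for agg in bundle["aggregated_units"]:
                fh.write(
                    f"{agg['label']}\taggregated shared-control rows: "
                    + "; ".join(agg["members"]) + "\n"
                )


# --------------------------------------------------------------------------
# Reference reproduction surface: published pooled results recomputed from
# the packaged study table.  ``expected`` values are the published numbers
# (2-decimal ORs) used only for comparison; every ``value`` is recomputed.

REFERENCE_CHECKS: tuple[dict, ...] = (
    {"id": "t1", "snp": "rs762551", "kind": "overall", "expected_or": 1.03},
    {"id": "t2", "snp": "rs762551", "kind": "stratum", "factor": "tumour_site",
     "level": "bladder", "expected_or": 0.84},
    {"id": "t3", "snp": "rs2472304", "kind": "overall", "expected_or": 0.84},
    {"id": "t4", "snp": "rs2472304", "kind": "stratum", "factor": "ethnicity",
     "level": "Caucasian", "expected_or": 0.72},
    {"id": "t5", "snp": "rs2472304", "kind": "stratum", "factor": "sample_size",
     "level": "large", "expected_or": 0.79},
    {"id": "t6", "snp": "rs2470890", "kind": "overall", "expected_or": 1.11},
    {"id": "t7", "snp": "rs2470890", "kind": "stratum", "factor": "ethnicity",
     "level": "Mixed", "expected_or": 1.44},
    {"id": "t8", "snp": "rs2470890", "kind": "loo", "omit": "Anderson LN 2012",
     "expected_or": 1.06},
    {"id": "t9", "snp": "rs2069514", "kind": "overall", "expected_or": 0.99},
    {"id": "t10", "snp": "rs2069514", "kind": "loo", "omit": "B'chir F. 2009",
     "expected_or": 0.93},
    {"id": "t11", "snp": "rs2069526", "kind": "overall", "expected_or": 0.94},
    {"id": "t12", "snp": "rs35694136", "kind": "overall", "expected_or": 1.37},
)


def compute_reference_value(check: dict, records: list | None = None) -> tuple[float, int]:
    """Recompute one reference quantity from the study table.

    Returns ``(pooled OR, number of pooled units)`` at full precision.
    """
    if records is None:
        records = study_io.load_fixture(check["snp"])
    else:
        records = [r for r in records if r.snp_id == check["snp"]]
    model = DEFAULT_MODELS.get(check["snp"])
    kind = check["kind"]
    if kind == "overall":
        units = study_io.build_analysis_units(records, model=model, aggregate=True)
        res = pooling.random_effects_pool([u.effect for u in units])
        return res.odds_ratio, res.k
    if kind == "stratum":
        by_level = pooling.subgroup_analysis(records, check["factor"], model=model)
        res = by_level[check["level"]]
        return res.odds_ratio, res.k
    if kind == "loo":
        units = study_io.build_analysis_units(records, model=model, aggregate=True)
        for label, res in pooling.leave_one_out([u.effect for u in units]):
            if label.startswith(check["omit"]):
                return res.odds_ratio, res.k
        raise ValueError(f"no leave-one-out iteration omits {check['omit']!r}")
    raise ValueError(f"unknown check kind {kind!r}")


def reference_report(records: list | None = None) -> pd.DataFrame:
    """Recompute every reference check and compare with the published value."""
    if records is None:
        records = study_io.load_fixture()
    rows = []
    for check in REFERENCE_CHECKS:
        value, k = compute_reference_value(check, records=records)
        rows.append({
            "id": check["id"],
            "snp_id": check["snp"],
            "kind": check["kind"],
            "detail": check.get("level") or check.get("omit") or "",
            "k": k,
            "or": round(value, 2),
            "expected_or": check["expected_or"],
            "pass": round(value, 2) == check["expected_or"],
        })
    return pd.DataFrame(rows)
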