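"""Study-table data model and CSV round-trip.

One row = one study stratum for one SNP: metadata, case/control totals and
either a full genotype table or a published crude OR with its 95% CI.  The
packaged fixture (``data/table1_fixture.csv``) is the hand-transcribed
reference table the reproduction surface runs against.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

ETHNICITIES = ("Caucasian", "Asian", "Mixed")
DESIGNS = ("population", "hospital", "gwas")
TUMOUR_SITES = (
    "bladder", "breast", "colorectum", "endometrium", "liver", "lung",
    "lymphoma", "ovaries", "pancreas", "pleura", "prostate", "stomach",
    "testicles", "thyroid", "head-and-neck", "UADT",
)
SAMPLE_SIZE_CUTOFF = 200  # cases; strictly greater -> "large"

CSV_COLUMNS = [
    "snp_id", "author", "year", "tumour_site", "country", "ethnicity",
    "design", "n_cases", "n_controls",
    "cases_wtwt", "cases_wtmt", "cases_mtmt",
    "controls_wtwt", "controls_wtmt", "controls_mtmt",
    "reported_or", "reported_lcl", "reported_ucl", "reported_model",
    "shared_control_group",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies: wild-type homozygous / heterozygous / mutant homozygous."""

    cases_wtwt: int
    cases_wtmt: int
    cases_mtmt: int
    controls_wtwt: int
    controls_wtmt: int
    controls_mtmt: int

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @property
    def n_cases(self) -> int:
        return self.cases_wtwt + self.cases_wtmt + self.cases_mtmt

    @property
    def n_controls(self) -> int:
        return self.controls_wtwt + self.controls_wtmt + self.controls_mtmt


@dataclass(frozen=True)
class StudyRecord:
    snp_id: str
    author: str
    year: int
    tumour_site: str
    country: str
    ethnicity: str
    design: str
    n_cases: int
    n_controls: int
    genotype_counts: GenotypeCounts | None = None
    reported_or: float | None = None
    reported_lcl: float | None = None
    reported_ucl: float | None = None
    reported_model: str = "recessive"
    shared_control_group: str = ""
    true_log_or: float | None = None  # simulation truth; never in the public CSV

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.tumour_site not in TUMOUR_SITES:
            raise ValueError(f"unknown tumour site {self.tumour_site!r}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        has_ci = (
            self.reported_or is not None
            and self.reported_lcl is not None
            and self.reported_ucl is not None
        )
        if self.genotype_counts is None and not has_ci:
            raise ValueError(
                f"{self.label}: need genotype counts or a reported OR with CI"
            )
        if has_ci:
            if not (0 < self.reported_lcl < self.reported_ucl):
                raise ValueError(f"{self.label}: invalid CI bounds")
            if not (self.reported_lcl <= self.reported_or <= self.reported_ucl):
                raise ValueError(f"{self.label}: OR outside its own CI")
        gc = self.genotype_counts
        if gc is not None:
            if gc.n_cases != self.n_cases or gc.n_controls != self.n_controls:
                raise ValueError(
                    f"{self.label}: genotype counts do not sum to the stated sample sizes"
                )

    @property
    def label(self) -> str:
        return f"{self.author} {self.year}, {self.tumour_site}"


def classify_sample_size(record: StudyRecord) -> str:
    """``large`` iff the study has strictly more than 200 cases."""
    return "large" if record.n_cases > SAMPLE_SIZE_CUTOFF else "small"


def _parse_row(row: dict[str, str], line: int) -> StudyRecord:
    def opt_float(key: str) -> float | None:
        v = (row.get(key) or "").strip()
        return float(v) if v else None

    def opt_int(key: str) -> int | None:
        v = (row.get(key) or "").strip()
        return int(v) if v else None

    geno_vals = {k: opt_int(k) for k in (
        "cases_wtwt", "cases_wtmt", "cases_mtmt",
        "controls_wtwt", "controls_wtmt", "controls_mtmt",
    )}
    present = [v is not None for v in geno_vals.values()]
    if any(present) and not all(present):
        raise ValueError(f"line {line}: partial genotype counts")
    counts = GenotypeCounts(**geno_vals) if all(present) else None

    return StudyRecord(
        snp_id=row["snp_id"].strip(),
        author=row["author"].strip(),
        year=int(row["year"]),
        tumour_site=row["tumour_site"].strip(),
        country=row["country"].strip(),
        ethnicity=row["ethnicity"].strip(),
        design=row["design"].strip(),
        n_cases=int(row["n_cases"]),
        n_controls=int(row["n_controls"]),
        genotype_counts=counts,
        reported_or=opt_float("reported_or"),
        reported_lcl=opt_float("reported_lcl"),
        reported_ucl=opt_float("reported_ucl"),
        reported_model=(row.get("reported_model") or "recessive").strip(),
        shared_control_group=(row.get("shared_control_group") or "").strip(),
    )


def read_study_table(path: str | Path, strict: bool = True) -> list[StudyRecord]:
    """Read a study-table CSV, validating every row.

    In strict mode a bad row raises; otherwise it is skipped with a logged
    reason.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[StudyRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: malformed header, missing columns {missing}")
        for line, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, line))
            except (ValueError, KeyError) as exc:
                if strict:
                    raise ValueError(f"{path}:{line}: {exc}") from exc
                logger.warning("skipping %s:%d: %s", path, line, exc)
    return records


def write_study_table(
    records: list[StudyRecord], path: str | Path, include_truth: bool = False
) -> None:
    """Write records back to the documented CSV schema (UTF-8, comma, dot decimals)."""
    columns = CSV_COLUMNS + (["true_log_or"] if include_truth else [])
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(columns)
        for r in records:
            gc = r.genotype_counts
            row = [
                r.snp_id, r.author, r.year, r.tumour_site, r.country,
                r.ethnicity, r.design, r.n_cases, r.n_controls,
                *(("", "", "", "", "", "") if gc is None else (
                    gc.cases_wtwt, gc.cases_wtmt, gc.cases_mtmt,
                    gc.controls_wtwt, gc.controls_wtmt, gc.controls_mtmt,
                )),
                "" if r.reported_or is None else f"{r.reported_or:g}",
                "" if r.reported_lcl is None else f"{r.reported_lcl:g}",
                "" if r.reported_ucl is None else f"{r.reported_ucl:g}",
                r.reported_model,
                r.shared_control_group,
            ]
            if include_truth:
                row.append("" if r.true_log_or is None else repr(r.true_log_or))
            writer.writerow(row)


def fixture_path() -> Path:
    return Path(resources.files("snpmeta.data") / "table1_fixture.csv")


def load_fixture(snp_id: str | None = None) -> list[StudyRecord]:
    """Load the packaged reference study table, optionally filtered to one SNP."""
    records = read_study_table(fixture_path())
    if snp_id is not None:
        records = [r for r in records if r.snp_id == snp_id]
    return records


@dataclass(frozen=True)
class AnalysisUnit:
    """One poolable unit: a single study or a merged shared-control group."""

    label: str
    effect: "object"  # EffectEstimate; typed loosely to avoid an import cycle
    records: tuple[StudyRecord, ...]

    @property
    def is_aggregate(self) -> bool:
        return len(self.records) > 1


def build_analysis_units(
    records: list[StudyRecord],
    model: str | None = None,
    aggregate: bool = True,
) -> list[AnalysisUnit]:
    """Turn records into poolable units, merging shared-control groups.

    Rows sharing a non-empty ``shared_control_group`` reuse one control
    series, so they are collapsed into a single unit whose effect is the
    DerSimonian-Laird combination of the member log-ORs (between-member
    spread is genuine heterogeneity across tumour sites, and only this
    combination reproduces the published overall pools).  Tumour-site
    stratified analyses pass ``aggregate=False`` to keep sites separate.
    """
    from . import effects, pooling

    units: list[AnalysisUnit] = []
    groups: dict[str, list[StudyRecord]] = {}
    order: list[tuple[str, StudyRecord | None]] = []
    for rec in records:
        key = rec.shared_control_group
        if aggregate and key:
            if key not in groups:
                order.append((key, None))
            groups.setdefault(key, []).append(rec)
        else:
            order.append(("", rec))

    for key, rec in order:
        if rec is not None:
            units.append(
                AnalysisUnit(
                    label=rec.label,
                    effect=effects.effect_from_record(rec, model=model),
                    records=(rec,),
                )
            )
            continue
        members = groups[key]
        ests = [effects.effect_from_record(m, model=model) for m in members]
        if len(members) == 1:
            logger.info("shared-control group %r has a single member", key)
            units.append(AnalysisUnit(label=members[0].label, effect=ests[0], records=tuple(members)))
            continue
        merged = pooling.random_effects_pool(ests)
        label = f"{members[0].author} {members[0].year}"
        units.append(
            AnalysisUnit(
                label=label,
                effect=effects.EffectEstimate(y=merged.y, se=merged.se, label=label),
                records=tuple(members),
            )
        )
        logger.info("aggregated %d shared-control rows into unit %r", len(members), label)
    return units


def aggregate_shared_controls(
    records: list[StudyRecord], model: str | None = None
) -> list[AnalysisUnit]:
    """Shared-control aggregation (see :func:`build_analysis_units`)."""
    snps = {r.snp_id for r in records}
    if len(snps) > 1:
        raise ValueError(f"records span multiple SNPs: {sorted(snps)}")
    return build_analysis_units(records, model=model, aggregate=True)
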