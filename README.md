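# snpmeta

Case-control SNP association meta-analysis toolkit: study-table IO,
per-study effect extraction (genotype-table collapse or published OR/CI),
DerSimonian–Laird random-effects pooling with heterogeneity decomposition,
publication-bias diagnostics (Egger regression, Begg rank correlation),
Galbraith outlier detection, leave-one-out sensitivity, subgroup
stratification, and genotype-level simulation for calibration studies.

The package ships a hand-transcribed reference study table
(`snpmeta/data/table1_fixture.csv`: 112 rows across six SNPs) and a
reproduction surface that recomputes the published pooled odds ratios from
it.

## Library overview

| Module | Contents |
|---|---|
| `snpmeta.study_io` | `StudyRecord` / `GenotypeCounts`, CSV read/write, fixture loading, sample-size classification, shared-control aggregation |
| `snpmeta.effects` | 2×2 odds ratios, genotype collapse (dominant/recessive), OR/CI back-transformation, genetic-model selection, HWE test (chi-square + exact) |
| `snpmeta.pooling` | fixed-effect and DL random-effects pooling, Q / I² / tau², subgroup analysis, leave-one-out, Galbraith residuals, forest/results tables |
| `snpmeta.bias` | Egger and Begg tests, funnel-plot data export |
| `snpmeta.simulate` | seeded genotype-level study simulation under HWE, effect-level generators, publication-bias censoring |
| `snpmeta.pipeline` | end-to-end orchestration, report bundle, reference checks |

```python
import snpmeta as sm

records = sm.load_fixture("rs762551")
units = sm.build_analysis_units(records, model="recessive")
pooled = sm.random_effects_pool([u.effect for u in units])
print(round(pooled.odds_ratio, 2), pooled.ci, pooled.i2)
```

## Command line

```bash
snpmeta validate --input table.csv
snpmeta analyze --snp rs762551 --out out/          # full report bundle
snpmeta analyze --input table.csv --strata ethnicity --out out/
snpmeta simulate --seed 7 --allele-freq 0.3 --true-or 1.4 \
    --k-studies 20 --out sim.csv
snpmeta reference                                  # recompute vs published
```

`analyze` writes `summary.json`, `results.tsv`, per-SNP
`forest_*.csv` / `funnel_*.csv` / `galbraith_*.csv`, `leave_one_out.csv`,
`bias_tests.tsv` and `exclusions.log`. A YAML config mirroring the flags
can be passed with `--config`.

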