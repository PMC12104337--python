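# adsubtype

Data-driven subtyping of patients from two cortical imaging modalities
(tau-PET SUVr and cortical thickness), implemented as a tested, reusable
pipeline:

- **`adsubtype.synthetic`** — synthetic two-modality cohorts with planted
  4-cluster spatial abnormality patterns, a healthy-control reference group,
  configurable cross-modal discordance, covariates and longitudinal visits
  with cluster-specific annual slopes; full ground truth for
  parameter-recovery testing.
- **`adsubtype.normalization`** — vertex/ROI z-scores against the
  healthy-control reference, parcel aggregation, amyloid/tau positivity
  rules, centiloid conversion, temporal meta-ROI composite,
  cortex-to-hippocampus volume ratio, cohort inclusion filters.
- **`adsubtype.cluster`** — the methodological core: subject-similarity
  graph of pairwise correlations between z-score vectors,
  weighted-modularity Louvain with resolution parameter gamma, consensus
  clustering over seeded iterations via co-assignment matrix iteration, and
  a gamma search returning the smallest grid value with a target cluster
  count.
- **`adsubtype.stability`** — Rand Index / adjusted Rand Index and a
  leave-N-out stability protocol against the full-cohort consensus
  partition.
- **`adsubtype.compare`** — tau-vs-atrophy cluster allocation (chi-square),
  cross-modal Spearman correlation of cluster ROI profiles (sign-corrected),
  cluster-vs-rest contrast maps with max-statistic permutation FWE control,
  vertex-wise tau–thickness association maps.
- **`adsubtype.longitudinal`** — per-subject annual change rates (linear
  mixed model or per-subject OLS), HC-standardized change z-scores,
  Kruskal–Wallis cluster comparison with BH-FDR and Bonferroni pairwise
  follow-ups, clinical score transforms.
- **`adsubtype.pipeline` / `adsubtype.cli`** — single-config orchestration
  with deterministic master-seed fan-out and a machine-readable
  `report.json`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(exhaustive modularity oracle, brute-force Rand-Index checks,
planted-cluster recovery, gamma-search contract, leave-N-out stability,
cross-modal coupling recovery, FWE/FDR calibration, formula exactness).

## CLI

```sh
adsubtype simulate  --config cohort.yaml --seed 1 --out data/
adsubtype normalize --data data/ --out norm/
adsubtype cluster   --zscores norm/z_tau.tsv --target-k 4 --out partition_tau.tsv
adsubtype stability --zscores norm/z_tau.tsv --gamma 1.2 --out stability.tsv
adsubtype compare   --data data/ --tau-partition partition_tau.tsv \
                    --atrophy-partition partition_atrophy.tsv --out cmp/
adsubtype longitudinal --data data/ --tau-partition partition_tau.tsv --out long/
adsubtype run-all   --config config.yaml --seed 1 --out out/
```

`run-all` accepts a YAML config mirroring
`adsubtype.pipeline.DEFAULT_CONFIG` (unknown keys are rejected); every
table is written as TSV and summarized in `out/report.json` with a
provenance block (config hash, seed, versions).

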