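# tsescore

T-cell-to-stroma enrichment (TSE) scoring and evaluation for predicting
immune-checkpoint-inhibitor response from bulk RNA-seq, with a synthetic
cohort generator so the whole pipeline runs and is testable without any
controlled-access data.

## What it computes

Given a normalized (log-scale, e.g. variance-stabilized) genes × samples
expression matrix and a GMT file of gene signatures tagged `T-cell` /
`other-immune` / `stromal`:

1. **Median centering** — every gene is centered at its median across the
   cohort's samples. The score is therefore *cohort-relative*: adding or
   removing samples changes all scores.
2. **Signature scores** — per-sample mean of centered expression over each
   signature's genes (signatures under 50% gene coverage are dropped with a
   warning).
3. **Global signatures** — unweighted means of the T-cell member signature
   scores and of the stromal member signature scores (fixed published
   membership lists by default; data-driven AUC re-screening behind
   `--rescreen`).
4. **TSE score** — global T minus global stromal, categorized as
   **positive** (≥ 0.5), **negative** (≤ −0.5) or **neutral** (otherwise);
   the cutoff is configurable.

Companion modules cover the comparator covariates and the evaluation layer:

- `genomic_features` — TMB high/low (≥ 10 mut/Mb), APOBEC enrichment class
  (no / low / medium E ≥ 2 / high E ≥ 3), clonal mutation fraction
  (variant copy number > 0.75).
- `tcr_repertoire` — sample filter (> 100 total reads), clonotype size
  classes (rare / infrequent / frequent / hyper-frequent), Hill diversity
  (default order q = 1).
- `protein_score` — immunofluorescence analog:
  `log10(1+CD4) + log10(1+CD8) − log10(1+FAP%) − log10(1+PDPN%)`.
- `stats_inference` — midrank ROC/AUC, DeLong test for correlated AUCs,
  exact two-sided Fisher test (integer arithmetic), Wilcoxon/Kruskal–Wallis,
  Benjamini–Hochberg, logistic regression (IRLS with separation detection),
  Kaplan–Meier / log-rank / Cox (Efron ties, via lifelines).
- `synthetic_cohort` — planted three-group cohorts (T-cell-high / mixed /
  stroma-high) linking expression shifts to response probabilities
  (default 0.67 / 0.21 / 0.00), survival hazards, TCR evenness and marker
  densities. Deterministic per seed.

## CLI

```bash
tse simulate --config sim.yaml --out cohort/ --seed 1     # synthetic cohort
tse score --expr cohort/expression.tsv --gmt cohort/signatures.gmt \
          --out tse.tsv [--cutoff 0.5] [--rescreen --labels cohort/clinical.tsv]
tse protein --markers cohort/markers.csv --out protein.tsv
tse tcr cohort/tcr/*.tsv --out tcr.tsv [--q 1.0]
tse evaluate --scores tse.tsv --clinical cohort/clinical.tsv \
             --predictors tse,tmb,apobec --out report/
tse run --config run.yaml                                  # full pipeline
```

`tse run` writes per-sample `tse.tsv`, a `summary.json` (category counts,
response rates by category, ROC/AUC with pairwise DeLong p-values,
survival summaries, provenance with config hash and seed) and a stage-timing
log. Output is byte-identical across runs with the same config and seed.

Example `run.yaml`:

```yaml
out_dir: results/run1
seed: 7
cutoff: 0.5
predictors: [tse, tmb, apobec]
simulation:
  n_samples: 300
  effect_T: 1.5
  effect_S: 1.5
  seed: 7
```

File-backed runs replace `simulation:` with `expression_path`, `gmt_path`,
`clinical_path` and optionally `markers_path`.

## Input formats

- expression TSV: first column `gene_id`, header row of sample ids.
- GMT: `name TAB group TAB gene1 TAB gene2 ...` (group = `T-cell`,
  `other-immune` or `stromal`).
- clinical TSV: one row per sample; columns `response`, `os_time`,
  `os_event`, `pfs_time`, `pfs_event`, `tmb`, `apobec_E`, `apobec_detected`, …
- clonotype TSV per sample: `clonotype_id`, `reads` (AIRR-style names
  accepted via a column mapping).
- marker CSV: `sample`, `cd4_density`, `cd8_density`, `fap_area_pct`,
  `pdpn_area_pct`, `tissue_area_mm2`.

Gene id matching is exact and case-sensitive; harmonize identifiers upstream.
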