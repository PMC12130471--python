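# chaoscope

Analysis pipeline for peripheral-blood CD8⁺ T-cell immunophenotyping in
lung-cancer immunotherapy, built around the observation that patients
progressively accumulate CD27⁻CD28⁻ effector-memory CD8⁺ T cells
(DN-Tem) — a cytotoxic but proliferation-incompetent subset — and that
this accumulation predicts poor response to immune-checkpoint-inhibitor
(ICI) therapy.

The package is written for translational immunologists and
biostatisticians working with per-cell flow-cytometry tables, paired
single-cell TCR sequencing, and clinical outcome data. It provides:

- **Subset gating** — hierarchical CCR7 × CD45RA gates (Tn, Tcm, Tem,
  Temra) with CD27 × CD28 subgates (DP, SP27, SP28, DN) inside Tem and
  Temra, per-donor frequency profiles, and batch-normalised relative
  MFI (each subset's mean intensity divided by the reference healthy
  donor's naive-subset mean in the same batch). Positivity cutoffs are
  fit per (marker, batch) by a two-component Gaussian mixture on
  asinh-transformed intensities.
- **TCR repertoire statistics** — clonotypes from paired CDR3α/β amino-
  acid sequences; Shannon diversity H = −Σ pᵢ ln pᵢ, Pielou evenness
  J = H/ln S, clonality 1 − J; unique-clonotype counts; expansion
  classes (barely: 1 cell, intermediate: 2–10, heavily: >10); and
  virus-specificity calls requiring both chains to match VDJdb entries
  of the same epitope.
- **Gene-set module scoring** — per-cell mean expression of a gene set
  minus expression-matched control genes drawn from pooled-mean bins;
  per-donor averages within a cluster; healthy-relative scores; and
  correlation-based grouping of gene sets into ordered clusters
  (GSC1..k, most patient-elevated first).
- **Protein-marker pseudotime** — a deterministic differentiation
  ordering: z-scored markers → PCA → symmetric kNN graph → shortest
  path from the medoid of the naive root; per-(group, subset)
  pseudotime histograms, patient-minus-healthy proportion differences,
  and per-donor average pseudotime.
- **The quadrant biomarker** — pre-treatment DN-Tem (% of Tem) and
  DP-Temra (% of Temra) split donors into quadrants Q1–Q4 (Q4 = both
  low, predicted best responders; defaults 36%/17.2% for NSCLC,
  42%/11% for SCLC, or re-derived as the 80 % healthy quantile).
  Evaluation reports per-quadrant partial-response and
  durable-clinical-benefit rates with Wald (unclipped) and Wilson
  binomial CIs, Fisher's exact Q4-vs-Q1 tests, midrank ROC AUC of
  DN-Tem, and Kaplan–Meier curves with the Gehan–Breslow–Wilcoxon test.
- **A synthetic cohort generator** — per-donor subset compositions,
  log-normal marker modes with batch effects, singleton + power-law
  clone sizes, a GZMK⁺-like barely-expanded DN-Tem subpopulation in
  patients, block-structured gene programs, and outcomes drawn from a
  logistic response model on the true quadrant — so every stage is
  testable without patient data.

## Worked example

```python
from chaoscope import synthetic, gating, biomarker as bm

cfg = synthetic.SimulationConfig(
    n_healthy=20, n_patients=60, cells_per_donor=2000,
    seed=7, tem_concentration=15,
)
cohort = synthetic.simulate_cohort(cfg)

thr = gating.derive_marker_thresholds(cohort.cell_table, seed=7)
labeled = gating.classify_subsets(cohort.cell_table, thr)
profiles = gating.subset_frequencies(labeled)

res = bm.evaluate_biomarker(profiles, cohort.outcomes, cfg.thresholds)
print(res.quadrant_counts)
print("Q4 PR:", res.pr_rates["Q4"]["wald"].as_percent())
print("Q1 PR:", res.pr_rates["Q1"]["wald"].as_percent())
print("AUC:", round(res.auc_dn_tem_pr, 4))
```

prints

```
{'Q1': 24, 'Q2': 22, 'Q3': 6, 'Q4': 8}
Q4 PR: (37.5, 3.95, 71.05)
Q1 PR: (20.83, 4.59, 37.08)
AUC: 0.6858
```

Of the 60 simulated patients, 8 fall in Q4 (low DN-Tem, low DP-Temra)
and respond at 37.5% (Wald 95% CI 3.95–71.05%), versus 20.8%
(4.59–37.08%) in Q1 (high DN-Tem); the AUC of the DN-Tem frequency for
predicting response is 0.69. Thresholds can also be re-derived from
the healthy reference rather than fixed:
`bm.derive_group_threshold(healthy_profiles["dn_tem_pct"], q=0.8)`.

The same stages are available from the shell:

```sh
chaoscope simulate --out cohort/ --seed 7
chaoscope gate --cells cohort/cells.csv --out profiles.csv
chaoscope repertoire --contigs cohort/contigs.tsv --vdjdb cohort/vdjdb.tsv --out clones.csv
chaoscope biomarker --profiles profiles.csv --outcomes cohort/outcomes.csv \
    --disease NSCLC --out biomarker.json
chaoscope run --config pipeline.yaml --seed 7
```

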