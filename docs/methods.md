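# Methods

This note documents the models, numerical conventions and design
choices behind each stage, what the synthetic generator does and does
not emulate, and the known limitations.

## Subset gating

Cells are partitioned by two binary gates: CCR7 × CD45RA defines
Tn (+/+), Tcm (+/−), Tem (−/−) and Temra (−/+); within Tem and Temra,
CD27 × CD28 defines DP (+/+), SP27 (+/−), SP28 (−/+) and DN (−/−).
The partition is exhaustive and exclusive, and the tie rule is
deterministic: intensity ≥ threshold ⇒ positive (this matches the
"≥ threshold ⇒ hi" convention used for donor-level grouping).

Manual gates are replaced by automated thresholds: per (marker, batch),
a two-component Gaussian mixture is fit on asinh(x/cofactor)
(cofactor 150, the conventional flow-cytometry transform; intensities
themselves are never transformed for MFI statistics). The cutoff is
the point where the posterior probability of the upper component
crosses 0.5, found by interpolation on a fine grid between the two
component means and mapped back to the raw scale. Initialisation is
deterministic (means at the 25th/75th percentiles, fixed random
state), so thresholds are reproducible. When the components collapse
(mean separation below half the summed component SDs, or a vanishing
weight) the fit falls back to a quantile threshold (default median)
with a logged warning. At least 50 cells per (marker, batch) are
required for a mixture fit.

Relative MFI divides each (donor, subset, marker) mean intensity by
the mean intensity of the *reference healthy donor's naive (Tn) cells*
for the same marker in the same batch. This cancels any multiplicative
per-batch factor exactly, which is the tested batch-invariance
property; it requires the reference donor (with ≥ 1 Tn cell) in every
batch, mirroring the experimental design of carrying one healthy
reference through all experiments. MFI defaults to the arithmetic mean
(a geometric-mean option is provided).

Frequencies use three denominators: all CD8⁺ cells for Tn/Tcm/Tem/
Temra; the Tem count for the within-Tem block; the Temra count for the
within-Temra block. Empty denominators produce missing values, never
0/0. The two biomarker axes are `dn_tem_pct` (DN % of Tem) and
`dp_temra_pct` (DP % of Temra), kept on the 0–100 scale in files and
0–1 internally.

## TCR repertoire

A clonotype is the concatenated pair of CDR3α and CDR3β amino-acid
strings; matching is exact string equality after validation against
the 20-letter alphabet (no Hamming tolerance — the statistics are
about identity, not similarity). Cells missing either chain are
excluded from clone statistics and counted in a QC report; when a cell
reports several contigs per locus, the highest-abundance productive
contig is kept (the common 10x convention).

Diversity of a clone-size vector (n₁, ..., n_S): Shannon
H = −Σ pᵢ ln pᵢ in nats; Pielou evenness J = H/ln S for S ≥ 2;
clonality = 1 − J. A single-clone repertoire is maximally clonal by
convention (J := 0, clonality := 1). Expansion classes partition
clones by size: barely = 1 cell, intermediate = 2–10, heavily = > 10
("more than ten duplicates" read literally as size > 10; the boundary
is centralised in two module constants).

One subtlety worth recording: clonality is *not* monotone under every
concentration move. Transferring a cell to the largest clone increases
clonality whenever the donor clone survives (entropy is Schur-concave
at fixed S), but when the transfer empties the donor clone, S and
hence the ln S denominator drop and clonality can decrease (sizes
[2, 2, 1] → [3, 2] is the smallest counterexample). The property test
asserts the fixed-S version exhaustively and pins the counterexample.
This same interplay produces the headline uncoupling pattern: an
influx of singleton clones raises S (richness) while a concurrently
expanding large clone raises clonality, so both move up together.

Virus-specificity requires *both* chains to match reference entries of
the *same* epitope: CDR3α equal to a TRA entry, CDR3β equal to a TRB
entry, with a shared epitope identifier; all qualifying epitopes are
reported. Matching is on CDR3 + epitope only (no MHC or species
constraint).

## Gene-set module scores

Genes are ranked by pooled mean expression and cut into `n_bins`
equal-size bins (default 24); for each target gene, up to `n_ctrl`
(default 100) control genes are drawn uniformly without replacement
from its bin, excluding the target itself. The per-cell score is
mean(target genes) − mean(pooled control genes). Matching controls on
expression level makes a random gene set score zero in expectation and
makes the score approximately invariant to per-cell depth offsets.
The control draw is seeded and therefore reproducible.

Donor-level analysis averages per-cell scores over one cluster
(typically the DP-Tem cluster, the precursor population of interest);
donors absent from the cluster are flagged missing rather than
imputed. Relative scores subtract the healthy-donor mean *within the
same dataset*, so the healthy mean is exactly zero per set and per
dataset by construction, and cross-dataset batch offsets cancel.

Gene-set clusters (GSC) group the sets-by-donors average-score matrix
by hierarchical clustering with correlation distance (1 − Pearson
across donors) and average linkage, cut at k (default 4). Cluster
labels are ordered by decreasing mean patient-minus-healthy score, so
GSC1 is always the most patient-elevated cluster and GSC-k the most
healthy-elevated. The procedure replaces an unspecified manual
categorisation and is the package's own choice. Missing values are
imputed by the set mean (logged).

## Protein-marker pseudotime

The trajectory stage deliberately avoids stochastic embeddings. The
pipeline is: per-marker z-score across all cells (scaled, not
normalised; constant markers dropped) → PCA to d components (default
5, full SVD, deterministic up to sign, which distances ignore) →
symmetric k-nearest-neighbour graph (default k = 15, Euclidean edge
weights, ties broken by cell index) → root at the medoid of the root
subset (naive T cells) → pseudotime = single-source shortest-path
distance, min–max scaled to [0, 1]. Unreachable cells get missing
pseudotime and are counted. The default marker panel is the ten
measured channels (CD8, CD3, CXCR4, CD45RA, CD95, CD27, CD28, CD73,
CCR7, CXCR3).

When comparing groups, the root can be narrowed to the *healthy* naive
cells (`root_mask`). This anchors the origin at the healthy pole of
the naive cloud; without it, the medoid of a mixed naive population
drifts toward the patients' shifted cells and the comparison loses its
reference point. The subset-ordering property (Tn < Tcm < DP-Tem <
DN-Tem in mean pseudotime) holds for either root on monotone data.

Distribution comparisons bin pseudotime into B equal-width intervals
on [0, 1] (default 50), normalise per (group, subset), and subtract:
diff = patient − healthy, which sums to zero by construction. "One
interval per subset" summaries are available via the per-donor,
per-subset average pseudotime.

## Quadrant biomarker

Thresholds: fixed disease defaults (NSCLC: DN-Tem 36%, DP-Temra 17.2%;
SCLC: 42%, 11%) or the empirical q-quantile (default 0.8, linear
interpolation) of a healthy reference of at least five donors — "higher
than most (~80%) healthy individuals". Quadrants: Q1 = DP-Temra lo /
DN-Tem hi; Q2 = hi/hi; Q3 = DP-Temra hi / DN-Tem lo; Q4 = lo/lo
(predicted best responders). The hi/hi corner naming is configurable
since conventions differ between plots and text.

Proportion CIs: the Wald interval p̂ ± z·√(p̂(1−p̂)/n) is deliberately
*not* clipped to [0, 1] — clinical reports print such intervals
(e.g. an upper bound of 107.3% for 11/12) and clipping would break
reconstruction; the Wilson score interval is bounded and is the better
small-sample choice. Both are always computed; every report states its
method. z = 1.959964 at the default 95% level.

Fisher's exact test uses the probability-mass two-sided convention
(sum of fixed-margin table probabilities ≤ that of the observed
table); a tail-doubling variant is exposed but non-default. A zero
margin yields p = 1 with a warning. The test is exact and therefore
conservative: under a null simulation its p-values are super-uniform
(an atom at p = 1), so calibration is asserted as "no excess of small
p-values / type-I error ≤ nominal", not as two-sided uniformity.

ROC AUC uses the midrank formula (identical to Mann–Whitney
U/(n₁n₀)); DN-Tem scores are negated internally so AUC > 0.5 always
means "lower DN-Tem predicts response". A Hanley–McNeil SE interval is
optional. Survival comparisons use Kaplan–Meier estimates and the
Gehan–Breslow-Wilcoxon test (log-rank weighted by the number at risk,
emphasising early differences), with an exhaustive or sampled
permutation p-value for small samples (n < 30 by default).

Durable clinical benefit (DCB) is PR or SD maintained at 6 months; CR
counts as benefit; a missing 6-month response propagates as missing,
never as "no benefit".

## Synthetic cohort generator

The generator's defaults are the study conditions used throughout the
tests: 50 healthy + 50 patient donors, 5,000 cells per donor, DN-Tem
within-Tem means 0.30 (healthy) vs 0.50 (patients), DP-Temra means
0.15 vs 0.18, quadrant PR rates 0.45 (Q4) vs 0.18 (Q1), clone
singleton fraction 0.6 with a power-law expanded tail (exponent 2.5),
5% virus-tagged clones, and half of patient DN-Tem cells GZMK⁺-like.

- **Compositions.** Per-donor subset and memory-subset compositions
  are Dirichlet draws around the group means (concentration 100,
  giving a donor-level SD of ≈ 0.046 on a 0.30 mean — wide enough that
  the healthy 80th percentile lands near the fixed 36% threshold,
  narrow enough for ±0.03 group-mean recovery at 50 donors). Counts
  are fixed by largest-remainder rounding, so per-donor subset counts
  sum exactly to the cell total. A per-stage additive logit shift on
  the DN component is available (default 0).
- **Markers.** Each (subset, marker) is a positive or negative
  log-normal mode (ln-scale means ln 100 and ln 10 000, σ = 0.5 —
  > 2σ separation, so gates are recoverable at ≥ 99%), with modes
  encoding the gating definitions plus a monotone differentiation axis
  (CD95 rises; CD73 and CXCR3 fall). Batch effects are multiplicative
  MFI factors; the reference healthy donor's cells are split across
  all batches. GZMK⁺-like DN-Tem cells get an intermediate CD27/CD28/
  CD73 profile (between the modes, below threshold) and carry
  singleton clones — the barely-expanded transitional population.
- **Activation drift.** Under `activation_drift > 0`, each patient
  cell is interpolated part-way toward the mode profile of the next
  subset on the differentiation chain (Tn→Tcm→DP-Tem→DN-Tem;
  SP→DN; Temra DP→DN), with a per-cell exponential mixing weight
  capped at 0.8. The skew matters: most cells stay near their own
  mode and a tail is already en route, so per-subset pseudotime shifts
  later in patients without moving the whole cloud (a uniform shift
  would drag the root medoid along and cancel the comparison).
- **Clones.** Singleton cells are fixed by the configured fraction;
  remaining cells are covered by power-law clone sizes (support
  s ≥ 2, last clone truncated to conserve the total exactly). CDR3
  strings are random AA strings; a configured fraction of clones is
  tagged with pairs from a small built-in *synthetic* VDJdb-style
  reference (each pair used at most once per donor so reconstruction
  is exact).
- **Expression.** A per-donor subsample of cells with three 30-gene
  programs — quiescence-like (up in healthy), activation-like (up in
  patients), inflammation-like (up in a random half of patients) —
  over 60 background genes; values are clipped-at-zero Gaussians.
  Note that because quiescence and activation shift in opposite
  directions and share expression bins, the *marginal* healthy-minus-
  patient quiescence-score difference on the full generator is larger
  than the single-block effect size; single-block recovery is tested
  on an isolated design.
- **Outcomes.** PR probability is logistic(intercept + quadrant
  log-odds) on the donor's *true* quadrant; non-responders split
  SD/PD; DCB is implied for responders and sampled for SD; PFS is
  exponential per quadrant with fixed administrative censoring at 730
  days. Healthy donors get outcome rows with missing responses so the
  cohort join is total.
- **Reproducibility.** One root seed; per-donor substreams are
  `default_rng([seed, donor_index])`, so output is bit-identical for a
  fixed config and donor-level under reordering.

What the generator does *not* emulate: spectral spillover and
compensation artefacts, doublets and debris, ambient RNA, realistic
transcriptome-wide count distributions, age structure, or correlation
between repertoire and marker state beyond the GZMK⁺ singleton rule.
Passing tests therefore demonstrate that the statistics recover the
structure they assume — not that real cytometry preprocessing is
handled.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: the default cohort
(100 donors × 5,000 cells) for gating/conservation/recovery checks; an
exhaustive Fisher enumeration over all 2×2 tables with N ≤ 30
(≈ 44,500 tables); 200 random 12-donor sets for the AUC oracle; all
clone-size partitions with S ≤ 5, N ≤ 12 for the diversity oracles;
500 null replicates at n = 500/arm for exact-test calibration; and a
16-donor, 800-cell cohort with drift 0.3 for the trajectory patterns.
Tolerance conventions: probability-vector sums to 1 within 1e-9;
group-mean recovery within ±0.03 (≈ 3 Monte-Carlo SEs at the default
sizes); directional claims asserted as strict inequalities.

## Known limitations

- Gate placement is automated; on strongly overlapping marker modes
  the mixture cutoff is a biased estimate of any manual gate, and the
  ≥ 99% recovery guarantee applies only to well-separated modes.
- Pseudotime is a graph geodesic, not a fitted principal curve; it
  preserves ordering on monotone manifolds but has no branch model.
- The GSC clustering substitutes for an unspecified manual
  categorisation; only the ordering semantics (GSC1 most
  patient-elevated) is guaranteed.
- Wald intervals are reported unclipped by design and can exceed
  [0, 100]%; use Wilson when bounds must be proper probabilities.
- The generator's outcome model conditions on the true quadrant only;
  it cannot represent confounding between marker noise and outcome.
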