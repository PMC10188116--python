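# Methods

## Scope and data model

The package analyzes a two-sample (young vs old) single-cell RNA-seq
experiment on sorted immune cells. Inputs are raw UMI count matrices in
the 10x triplet layout (genes × cells; MatrixMarket coordinate file with
features/barcodes listings), a per-cell cluster assignment produced by
any external clustering, a literature marker panel (cell type → marker
genes), a directed ligand→receptor pair table, and gene lists (chemokine,
cytokine, SASP-receptor sets). Clustering, embeddings, reference-profile
annotation, differential-abundance testing and GO enrichment are outside
the package: they depend on external algorithms, databases or services,
and their outputs are treated as inputs where needed (cluster IDs, term
lists).

## Quality control

A cell is removed when it detects fewer than `min_features` genes
(default 200), more than `max_features` (default 2500), or when
mitochondrial genes carry more than `max_mito` (default 10%) of its raw
counts. Boundaries follow the strict inequalities, so exactly 200, 2500
and 10.0% are retained. "Detected" means raw count > 0; the mitochondrial
proportion is computed on raw counts over all genes (the standard
interpretation; a detected-feature-share reading is conceivable but not
common practice, and the threshold is configurable). Mitochondrial genes
are recognized by the case-insensitive name prefix `mt-` (mouse
convention; configurable). The QC report attributes each removed cell to
its first failing rule in the order low/high/mito. The filter is
idempotent.

## Normalization

LogNormalize with scale 10 000 and the natural logarithm:
`x_gi = ln(1 + 10^4 · c_gi / T_i)` with `T_i` the cell's total count.
Zeros map to zeros, values are monotone in the raw count within a cell,
and per-cell scaling makes the values depth-invariant. Cells with zero
total cannot be normalized and raise an error naming the barcode (QC
removes them first in the pipeline).

## Marker scores and cluster identity

For marker gene g, cell i in cluster c:

    S_gic = (E_gi − m_g) / (M_g − m_g) · N_gc / N_c

with E the raw count, M_g/m_g the max/min of g across all cells of the
sample (each sample is scored independently), N_c the cluster size and
N_gc the number of cluster cells with count above the expression
threshold (0 by default; the same threshold is used for both factors).
Scores lie in [0, 1]; a gene constant across the sample or absent from
the matrix scores 0 with a warning. Cluster evidence for a candidate
type is the mean score of that type's markers over the cluster's cells;
the call is the argmax, with lexicographic tie-break (logged). When an
external per-cell reference label is supplied, the cluster's modal
reference label is recorded with an agreement flag; the marker call
wins and disagreements are surfaced rather than auto-resolved, because
reconciling the two sources is a judgement call the analyst should see.

## Differential expression

Per cell type, old vs young, over genes detected in at least 3 cells of
the type (both ages pooled):

* fold change `fc_g = (mean_old + ε) / (mean_young + ε)` on normalized
  means, ε = 1e-9 (guards empty denominators only; raw-count means are
  available by passing the raw matrix, and parameter-recovery checks use
  that scale since a planted fold is defined on counts);
* two-tailed Student t-test with pooled variance; genes with zero
  variance in both groups get p = 1;
* Storey q-values with the smoother-free π0 estimate
  `π0 = mean_λ #{p > λ} / (m(1−λ))`, λ ∈ {0.05, …, 0.95}, clipped into
  (0, 1]; `q_(i) = min_{j≥i} π0 m p_(j)/j`, monotone in p. With fewer
  than 10 p-values π0 falls back to 1 (the Benjamini–Hochberg limit).
* DEG = (fc ≥ 2 or ≤ 1/2) ∧ p ≤ 0.05 ∧ q ≤ 0.1. Direction reflects the
  fold alone.

The tail-restricted variant flags genes at or below the 2.5% quantile or
at or above the 97.5% quantile of the cell type's empirical fold-change
distribution ("in_tail"), so that calls driven by a global shift of the
whole distribution can be discounted; the quantile reading of the 2.5%
tail mass is this module's main interpretive decision and is isolated in
one operation. A degenerate (constant) fold distribution flags nothing.
Term-list post-processing labels an enrichment term "global" when it
appears in ≥ 2 cell types (per direction), else "specific".

## Gene-set shift tests

A set's per-gene statistics (fold changes, or detection-rate differences)
are compared to the all-gene background two ways: a two-sample
Kolmogorov–Smirnov test (exact p when both n ≤ 25, asymptotic otherwise)
against all tested genes — the literal reading of comparing the set CDF
to the all-gene CDF — and a resampling null of `n_resample` (default
10 000) random same-size sets drawn without replacement from the tested
genes, summarized as the percentile of the observed set median among the
resampled medians (ties counted half). The median was chosen as the
resampling summary for robustness; the KS test carries the significance
statement, the percentile is an auxiliary diagnostic. KS D is invariant
to monotone transforms, so ratio vs log2 fold scale does not matter.

Composition fractions per age come with Wilson score 95% intervals
(normal-approximation intervals available); Wilson behaves well at the
small fractions typical for rare cell types.

## Ligand–receptor network

An edge (ligand → receptor) is flagged for a direction when the ligand
is a DEG with that direction in ≥ 1 cell type and the receptor is a DEG
with the same direction in ≥ 1 cell type (possibly the same). The full
DEG rule (fold + p + q) defines "significant", matching the heat-map
criterion the edge rule builds on; the primary (not tail-restricted) DEG
set is used. The chord summary counts flagged edges per (ligand type,
receptor type) pair, each edge contributing to the cross-product of its
endpoint type lists. The shipped pair table is a small curated snapshot
of canonical mouse chemokine/cytokine ligand–receptor pairings in the
scope of the cytokine–cytokine-receptor interaction pathway; users with
database access should substitute their own full table. Multi-subunit
receptors appear as one row per subunit gene, any of which can qualify.

## SASP-receptor detection rates

Expressed fraction = share of a cell type's cells (per age) with raw
count > 0. Per-gene change is tested by two-sided Fisher's exact test on
the 2×2 expressed × age table (chi-square behind a flag); significance
at α = 0.01. Set-level shift reuses the resampling machinery on
fraction differences. Multiplicity is assessed analytically under the
global null, where each gene is independently significant with
probability α:

* designated-set form: α^k — the probability that k *named* genes are
  all significant; k = 6, n = 24, α = 0.01 gives exactly 10⁻¹²,
  matching the headline probability this analysis reproduces;
* binomial tail: P(Bin(n, α) ≥ k) — the probability that at least k of
  the n set genes are significant (~1.15e-7 for the same parameters).

The two formulas bracket the loose "k of n significant" statement; both
are computed and labelled rather than silently choosing one. The shipped
24-receptor list is a constructed stand-in (see the `_synthetic` file
suffix): the receptors named in the aging-ovary literature plus
canonical receptors of well-known SASP factors.

## Synthetic-data generator

Counts are negative-binomial, `X ~ NB(μ, θ)` with
`P(X=0) = (θ/(θ+μ))^θ`, one global dispersion θ. Defaults define the
study conditions: 2000 genes; baseline mean 0.3 per gene per cell
(≈ 490 detected genes per cell, a realistic sparse-droplet regime);
θ = 2; six cell types (ILC1, Mph, NT, NK, DC, DNT) with 3307 young and
5468 old clean cells composed so the young sample is innate-dominated
(ILC1 35.4%, NK 9.8%, DNT 5.8%) and the old sample DNT-dominated
(35.8%, every innate fraction reduced); 3 markers per type at 8× the
baseline mean; 13 mitochondrial genes whose per-cell count share is
drawn uniformly from (0.01, 0.04), keeping clean cells clear of the 10%
QC boundary; planted QC violators appended per sample (386 young, 176
old, giving 3693/5644 loaded barcodes). Old-age plantings: chemokine and
cytokine sets halved (×0.5) in the innate types ILC1/NT/DC, with a focal
subset of ligand–receptor genes cut to ×0.25 so the twofold DEG rule and
hence the network rule engage; 8 genes ×4 and 8 genes ×0.25 per cell
type as DEG-recovery controls; the 24 SASP receptors raised from 0.30 to
0.50 detection probability in old macrophages.

Fraction plantings are zero-inflated on top of the NB:
`count = Bernoulli(f) · (1 + NB(μ, θ))`, so the detection probability is
exactly f while the conditional level tracks μ; where a (type, gene)
appears in both the DE and fraction plantings, the fraction planting
wins (the SASP receptors overlap the cytokine set, and their macrophage
planting is the detection-rate story). Each sample has its own RNG
stream seeded from (seed, sample offset): identical seeds give
bit-identical matrices.

Not emulated: ambient RNA, doublets, batch effects, library-size
confounding, per-gene dispersions, correlated gene programs. Passing
tests therefore demonstrate correctness of the statistical machinery
under a clean generative model, not robustness to those artifacts on
real data.

## Pipeline and determinism

Stages (qc → normalize → annotate → de → setshift → network → sasp →
composition) each read their inputs from disk and write plain TSV/JSON,
so any stage can be re-run in isolation; a failure aborts the run naming
the stage, retaining partial outputs. All randomness (resampling nulls)
derives stage seeds deterministically from the single config seed via
seed sequences; wall-clock timings are written to a separate
`timings.json` so every other output is byte-reproducible for a fixed
seed. The YAML config rejects unknown keys and range-checks every
threshold; defaults are 200/2500/0.10 (QC), fold 2 / p 0.05 / q 0.1
(DEG), α 0.01 and 10 000 resamples (set tests).

## Problem sizes used in the checks

The test suite runs the generator at reduced sizes chosen as the
package's own desk-scale conditions: annotation recovery at 4 types ×
60 cells over 20 seeds; DEG null calibration at 1000 genes × 200 cells
per group over 20 seeds and planted-fold recovery at 300 cells per
group; set-shift power at 2000 genes × 300 cells per group over 50
seeds and null-percentile uniformity at 1000 genes × 100 cells over 200
seeds; SASP power at 600 genes × 500 cells per group over 50 seeds; the
end-to-end run at 800 genes with 590/690 cells. `scripts/acceptance.py`
runs the full default conditions (2000 genes, 3693/5644 cells). The
documented end-to-end recovery tolerances are: ≥ 80% recall of strongly
planted (×4 / ×0.25) DEGs in types with ≥ 100 cells per group, 100%
cluster-identity recovery, exact QC/composition accounting, flagged
focal chemokine edges, and macrophage SASP significance (k ≥ 6 of 24).

## Known limitations

* The Fisher-exact per-gene detection test and the pooled-variance
  t-test assume independent cells; pseudoreplication within animals is
  not modelled (the underlying experiment pools cells per age group).
* π0 estimation is unstable for very small gene panels; the BH fallback
  is conservative.
* The α^k designated-set FWER presumes the k genes were named before
  testing; when k is chosen as the observed number of significant genes,
  the binomial tail is the honest quantity — both are reported.
* The curated ligand–receptor snapshot is far smaller than the full
  pathway map; edge counts scale with the table supplied.
* Marker-score annotation requires markers that are actually enriched;
  clusters with no marker signal are labelled `unresolved` and excluded
  from downstream per-type analyses.
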