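# Methods

`iltcniche` maps innate-like T-cell (iLTC) niches — γδT, MAIT and iNKT —
in spot-level spatial transcriptomics of psoriatic skin, and mirrors the
tissue analysis with a CITE-seq gating stage for blood. This note records
the models, the defaults and why, and what the synthetic testbed does and
does not establish.

## Spot model and deconvolution

A Visium spot captures a small mixed group of cells. On the linear scale its
depth-normalised expression is modelled as a nonnegative combination of
reference cell-type profiles,

    y ≈ R f,   f ≥ 0,

where `R` is the gene × cell-type reference with columns normalised to sum
to one over the genes shared with the dataset, and `y` is counts-per-10k.
Coefficients are estimated by nonnegative least squares (Lawson–Hanson
active set, `scipy.optimize.nnls`) and rescaled to proportions
`f / Σf`. Counts are deliberately *not* log-transformed before fitting:
the mixture model is additive in expression and the log breaks additivity.

UMI counts are overdispersed, and an unweighted fit lets the noise of a few
high-abundance genes dominate the stromal split (fibroblast vs
keratinocyte). The default fit is therefore iteratively reweighted: gene
variances are modelled as `s·μ + μ²·α` (negative-binomial mean–variance;
`s` the per-spot normalisation factor), with `μ` taken from the previous
pass and a single pooled method-of-moments `α` per dataset; each pass
solves the row-rescaled NNLS system. Six passes are run; the procedure
converges to the accuracy of an oracle fit that knows the true variances.
`weighting="none"` restores the plain unweighted fit.

Degenerate designs are handled deterministically: exactly duplicate
columns (equal after scaling to unit norm) are collapsed before the fit and
the coefficient is split equally afterwards; all-zero columns get
coefficient zero; both flag the spot `degenerate`. All-zero spots are
flagged `zero_spot` with zero proportions.

## Niche calling

Spots are gated on the deconvolved pan-T fraction (sum over the T-lineage
columns) with a per-sample adaptive threshold

    t_sample = max(quantile_q(T fractions of that sample), floor)

with defaults `q = 0.8` and `floor = 0.05`, and linear-interpolation
quantiles. The per-sample quantile absorbs differences in immune-cell
density and depth between sections; the floor stops immune-poor samples
from promoting background spots. The gate is inclusive (`≥`) so the
all-values-equal case is well defined. Samples with fewer than 10 spots
fall back to the floor.

Among gate-passing spots, each subset signature (γδT, MAIT, iNKT) is
scored on log-normalised expression (`log1p(count·10⁴/total)`), either as
the plain mean over the set's genes or control-corrected (mean of a
size-matched control pool drawn from 25 expression bins, 50 control genes
per signature gene, seeded). Scores are z-scored within sample so
signatures of different sizes are comparable, and the label is the subset
with the largest z-score provided it is positive; ties break by the larger
corresponding deconvolved subset fraction, then by the fixed order
γδT > MAIT > iNKT. Subsets without a signature are skipped with a warning,
which is also how datasets where iNKT cannot be assessed are handled.

Because the gate quantile passes a fixed share of each sample's spots,
samples with few genuine niches retain a noise-floor label rate; frequency
contrasts (lesional vs non-lesional) remain valid because the floor is
common, but absolute background frequencies should not be over-read.

Per-sample × layer niche frequencies are percentages of that cell's spot
count; cells under 20 spots are flagged `low_n`. Lesion/non-lesion ratios
pair samples by donor (naming convention `<donor>_L` / `<donor>_NL`, or an
explicit donor map) and replace a zero denominator with the pseudo-frequency
`100/(n_spots+1)`, flagged.

## Spatial statistics

Spatial weights are a binary k-nearest-neighbour graph (Euclidean, k = 6 to
match the hexagonal Visium packing), symmetrised by union, no self-edges;
ties in the distance ranking break by spot index so duplicated coordinates
are deterministic. Moran's I is

    I = (N/W) · Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²,   z = x − x̄,

with null expectation −1/(N−1). Inference is by seeded label permutation
with the two-sided +1/+1-corrected p-value
`(1 + #{|I_perm − E| ≥ |I_obs − E|})/(n_perm + 1)`, which is always in
(0, 1]. Constant fields return `I = NaN`, `p = 1` and a flag rather than
raising. By default I is computed on the binary niche-indicator field of
each subset within each sample × layer; a config switch allows continuous
scores.

The γδT–MAIT imbalance index is `z(epidermal MAIT %) − z(dermal γδT %)`,
z-scored across lesional samples only (PASI exists only for lesional
samples) with the n−1 denominator; fewer than 3 lesional samples or a
zero-variance component make it undefined. Severity associations are
Spearman rank correlations (average ranks, large-sample t approximation),
with pairs missing PASI dropped and counted, and no p-value below n = 4.

## Expression statistics

Differential expression between niche classes uses the two-sided Wilcoxon
rank-sum test per gene (tie-corrected normal approximation with continuity
correction; exact enumeration below a combined n of 20), log fold change
defined as the difference of group means of log-normalised expression, and
Benjamini–Hochberg adjustment over all tested genes. Genes expressed in
neither group are skipped and counted. Significance uses
|log FC| ≥ 0.25 (inclusive) and adjusted p < 0.05 (strict).
Over-representation of flat gene sets is the upper-tail hypergeometric test
against the universe of tested genes, BH-adjusted across sets and ranked by
GeneRatio (overlap/query) then adjusted p.

Group comparisons are distribution-gated: each group is screened with
Shapiro–Wilk at α = 0.05; if all groups pass, Student's t (two groups) or
one-way ANOVA with Tukey HSD (more); otherwise Wilcoxon rank-sum or
Kruskal–Wallis with pairwise rank-sum post hocs, BH-adjusted within the
post-hoc family. Groups under n = 3 force the nonparametric branch.

## CITE-seq stage

ADT counts are CLR-transformed with a +1 pseudo-count, per cell by default
(`clr(xᵢ) = ln(xᵢ+1) − mean_j ln(xⱼ+1)`), with a per-feature switch.
Gating is hierarchical and programmatic: each gate is strict positivity of
one marker's CLR value above a threshold AND membership of the parent gate.
Thresholds are either fixed CLR cutoffs or cohort quantiles computed once
over all cells, so every donor is gated identically. The shipped default
hierarchy (CD45 root; TCRγδ for γδT; CD161 then TCR-Vα7.2 for MAIT;
an invariant-TCR marker for iNKT) is an editable config default. Two
practical points shaped the quantile defaults: a quantile threshold must
sit *below* `1 − expected positive share` or it cuts into the positive
population by construction; and the per-cell CLR couples co-elevated
markers (two bright markers raise the cell mean and drag both CLR values
down), so two-marker AND gates need slightly more generous quantiles.

Subset frequencies are percentages of CD45⁺ cells per donor (donors under
50 CD45⁺ cells flagged); phenotype-marker positivity is reported within
each subset, missing and flagged for empty subsets. RNA–protein
concordance is the Spearman correlation between per-donor mean RNA
gene-set scores (among CD45⁺ cells) and the gated frequencies.

## Synthetic testbed

The generator provides ground truth for every stage.

* **Reference**: 300 genes × 6 cell types (fibroblast, keratinocyte, γδT,
  MAIT, iNKT, conventional T); each type gets 20 exclusive markers at 8×
  a log-normal(0, 1) baseline shared across types. With fold 1 the types
  are indistinguishable by construction (documented degenerate case).
* **Sections**: unit-spacing hexagonal lattice with offset rows; the top
  30% of spots by y form the epidermal band. Niche spots carry their
  subset at fraction 0.25 versus a background total T fraction of 0.05
  split across the four T lineages; the stromal remainder is
  keratinocyte-dominant in the epidermis and fibroblast-dominant in the
  dermis. Counts are negative-binomial with mean `depth · R f` (depth
  5000) and dispersion in the variance-inflation convention
  `var = μ + α μ²` with α = 0.5 by default; `dispersion=None` (or 0) is
  the Poisson limit. This convention is the package's definition of
  "dispersion" (statsmodels' alpha); the Poisson limit is at α → 0.
* **Cohorts**: 12 lesional donors with paired non-lesional samples and 6
  healthy controls. Lesional PASI is uniform on [2, 30]; planted links are
  linear — dermal γδT proportion 0.16 − 0.005·PASI (decreasing), epidermal
  MAIT 0.02 + 0.005·PASI (increasing) — plus Gaussian jitter (SD 0.02) on
  the proportion scale, clipped at 0 with a warning. Background niche
  proportions are 0.02 everywhere else (a free parameter of the generator:
  background iLTC abundance in healthy skin is not something the testbed
  takes from data). `generate_counts=False` returns only the planted
  sample table, which is all that sample-level statistics need; the
  severity-recovery replicates use that mode, while full count cohorts
  exercise the end-to-end path.
* **CITE-seq**: 12 donors × 2000 cells across HC/PsO/PsA (γδT reduced in
  psoriatic disease, MAIT increased in PsA); per-donor subset frequencies
  vary log-normally (log-SD 0.5 — conservative next to the ~10-fold
  inter-individual spread of human MAIT frequencies); subset cells have
  8-fold elevated counts on their positive markers; ADT counts are
  negative-binomial with α = 0.1, matching the clean bimodality of
  lineage-marker ADT distributions in real data. Per-donor mean RNA scores
  are planted to correlate with log frequency at ρ = 0.9 (the log scale is
  where the frequencies are Gaussian, so the planted value is what a rank
  correlation should recover).

All randomness flows from one top-level seed through fixed per-stage and
per-section child streams, so every output is reproducible bit-for-bit.

What the testbed does **not** emulate: spot bleed-over and doublets,
platform/batch effects between reference and tissue, histology-driven
layer segmentation error, ambient-antibody background and doublets in
ADT data, and any real correlation structure between genes beyond the
mixture itself. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistics under the stated generative
model, not performance on arbitrary real cohorts.

## Numerical and design choices

* NNLS tolerance is the solver's machine-level active-set criterion;
  solver-vs-oracle agreement is checked against exhaustive support
  enumeration on small instances.
* Quantiles use linear interpolation everywhere (thresholds, gates).
* Within-sample z-scores use the n−1 denominator; constant columns give
  z = 0 rather than NaN.
* CSV reports are written with a fixed float format (`%.10g`) and sorted
  keys, making identical-seed runs byte-identical.
* Problem sizes in the recovery and calibration suites (500-spot sections,
  1000 null fields × 199 permutations, 200 cohort/CITE-seq replicates,
  2000-gene DE panels) were chosen as the smallest sizes at which the
  Monte-Carlo error of each check is comfortably below its acceptance
  margin.

## Known limitations

* The adaptive T gate passes a fixed quantile share per sample, so
  absolute niche frequencies in niche-poor samples have a noise floor;
  contrasts and correlations are the supported read-outs.
* Deconvolution assumes the reference spans the spot's composition; cell
  types absent from the reference are projected onto the available ones.
* The imbalance index is a descriptive summary; it inherits the
  arbitrariness of z-scoring over whichever lesional cohort is supplied.
* Gating thresholds are cohort-quantile defaults meant to be edited per
  panel; they assume roughly stable marker distributions across donors.
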