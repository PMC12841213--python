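# iltcniche

Spot-level mapping of innate-like T-cell (iLTC) niches — γδT, MAIT and
iNKT — in spatial transcriptomics of inflamed skin, with the statistics
that link niche organisation to clinical severity, and a companion
CITE-seq stage for blood.

Psoriatic skin reorganises its unconventional T-cell compartments: γδT
programmes spread through dermis and epidermis while MAIT programmes
concentrate in the epidermis, and the two shift in opposite directions as
severity (PASI) rises. Testing such claims from Visium-class data takes a
chain of steps — cell-type deconvolution, adaptive niche calling,
layer-stratified frequencies, spatial autocorrelation, severity
correlations, and protein-level validation in blood — each easy to get
subtly wrong. `iltcniche` packages that chain as a tested, seeded pipeline
for anyone analysing spot-level skin transcriptomics with rare-population
signatures, together with a synthetic-cohort generator so every stage has
a ground-truth recovery test.

## The core model

Each spot's depth-normalised expression is a nonnegative mixture of
reference cell-type profiles, `y ≈ R f, f ≥ 0`, solved per spot by
(variance-weighted) nonnegative least squares; proportions are `f/Σf`.
Spots pass a per-sample adaptive pan-T gate,
`T_fraction ≥ max(quantile₀.₈, 0.05)`, and passing spots take the label of
the subset whose within-sample z-scored signature dominates (if positive).
Spatial patterning is Moran's I on 6-nearest-neighbour hex-lattice graphs
with permutation p-values; severity structure is summarised by Spearman
correlations with PASI and the imbalance index
`z(epidermal MAIT %) − z(dermal γδT %)` over lesional samples. ADT counts
are CLR-normalised (`ln(x+1) − mean ln(x+1)` per cell) and gated by a
reproducible cohort-quantile hierarchy. Details and defaults:
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a cohort with known ground truth (8 lesional donors with paired
non-lesional sections, 3 healthy controls, 300 spots per section, plus a
paired CITE-seq-like dataset), then run the full pipeline:

```bash
iltc simulate --seed 7 --out demo --n-lesional 8 --n-hc 3 --spots 300
iltc run --seed 7 --data demo --out demo_results \
    --adt demo/adt_counts.csv --adt-meta demo/adt_cells.tsv \
    --rna-scores demo/rna_scores.csv
```

`demo_results/severity_stats.csv` then contains (abridged):

```
        feature     layer    rho     p  n flag
        pct_gdT    dermis -0.892 0.003  8   ok
       pct_MAIT    dermis  0.024 0.955  8   ok
        pct_gdT epidermis  0.472 0.237  8   ok
       pct_MAIT epidermis  0.897 0.003  8   ok
imbalance_index            0.881 0.004  8   ok
```

The generator plants a dermal γδT proportion that falls with PASI and an
epidermal MAIT proportion that rises with it; the recovered rank
correlations (−0.89 and +0.90 across 8 lesional samples, both p ≈ 0.003)
and the strongly positive imbalance-index correlation (0.88) show the
whole chain — counts → deconvolution → gating → frequencies → statistics —
recovering the planted structure, while the unlinked cells (dermal MAIT,
epidermal γδT) stay near zero. The companion
`demo_results/cite_concordance.csv` reports per-subset Spearman agreement
between gated ADT frequencies and RNA scores across 12 donors
(ρ ≈ 0.71–0.76 here, planted at 0.9 before measurement noise).

Other reports: `niche_calls.csv` (per-spot labels, scores and the
thresholds that produced them), `fractions.csv` (deconvolved
proportions), `sample_summary.csv` (per-sample × layer frequencies and
module scores), `moran.csv` (spatial autocorrelation per sample, layer and
subset), `imbalance.csv`, `de_table.csv` and `enrichment.csv`
(γδT-vs-MAIT niche differential expression and gene-set
over-representation), `cite_summary.csv` (per-donor gated frequencies).

The same stages are importable as a library (`iltcniche.deconvolution`,
`.niche`, `.spatial`, `.expression`, `.cite`, `.synthetic`) for use on
real matrices.

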