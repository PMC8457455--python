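# Methods

This document specifies the statistical model, parameter conventions,
noise-model choice, numerics and limitations of `chromage`.

## Genome model

Genomes are dictionaries of chromosome lengths with optional
compartment annotations (e.g. `arm` / `center`); all intervals are
0-based half-open. Regions are assigned to a compartment by the
compartment containing their midpoint. Gene/region overlap uses a
≥ 1 bp rule on the half-open coordinates.

## Coverage tracks and the z-scored ratio

`bin_coverage` piles up reads into fixed-width bins (default 20 bp),
extending each read to 200 bp from its 5′ end. `log2_ratio_track`
computes `log2((mark + 0.5) / (control + 0.5))` after boxcar smoothing
with a window of `smooth` bp (default 60) and scaling both tracks to
their geometric midpoint so the ratio is depth-independent; bins where
both tracks are zero are masked. `zscore_track` standardises the valid
bins with the **population** SD (ddof = 0): for values (1, 2, 3) the z
scores are (−1.2247, 0, +1.2247). Replicate agreement is assessed as
the Pearson correlation of read counts in 15 kb windows, the scale at
which broad-domain signal is coherent; raw fine-bin correlations are
systematically lower because they are dominated by counting noise.

## Broad-domain reconstruction

Peak callers fragment broad repressive domains. `merge_adjacent_peaks`
joins two adjacent peaks when the gap between them is strictly shorter
than `max_gap` (default 5000 bp) **and** the mean z-scored ratio across
the gap is strictly positive. Book-ended peaks (gap 0) always merge;
gaps that are fully masked or have non-positive mean never merge.
Merging is applied left to right transitively; because joining two
peaks never alters any neighbouring gap, the single pass is provably
equal to the fixpoint of exhaustive pairwise merging (the test suite
checks this against a brute-force oracle). `gap_threshold_scan`
reports the merged count across a ladder of thresholds; on data whose
intra-domain gaps all lie below 5 kb the count plateaus at the true
domain number.

## Double-contrast differential enrichment

For each region and replicate, the paired log ratio is

```
R = log2((k_mark + 0.5) / N_mark) − log2((k_ctrl + 0.5) / N_ctrl)
```

with `N` the sample library size. The age effect per region is
`delta = mean(R_old) − mean(R_young)` — algebraically the double
contrast (old mark − old H3) − (young mark − young H3). Regions with
zero mark counts in every sample are excluded and reported.

Variance moderation follows the empirical-Bayes moment approach on the
log variance scale: per-region variances `s²` (df = n_young + n_old − 2)
are shrunk toward a prior `s0²` with prior df `d0` estimated from the
spread of `log s²` in excess of the theoretical chi-square spread;
when the observed spread does not exceed it, `d0 = ∞` and all regions
share `s0²`. The moderated t uses
`s̃² = (d0·s0² + df·s²)/(d0 + df)` with `d0 + df` degrees of freedom.
P-values are two-sided and BH-adjusted (`q`); `direction` is `up`/`down`
for `q < alpha` (default 0.05), else `ns`.

**Composition handling.** For the ChIP feature set, per-column medians
of `R` are subtracted before contrasting (robust centering): the
most-regions-unchanged assumption holds there, and without it genuine
ASRR gains inflate the old library totals and bias stable regions
toward "down". For repeat RNA, centering is *disabled* and library
sizes are the whole-transcriptome mapped totals: the expressed-repeat
feature set can legitimately be dominated by changing loci, which
violates the centering assumption, and repeat output genuinely rises
with age so normalising within the repeat compartment would erase the
signal being measured.

## ASRR classification

A region is an aging-specific repressive region when `direction == up`
and its mean young-age z-scored ratio is below `asrr_z_max` (default
0.0) — it gains repressive mark with age *and* was not repressive in
young animals. Fold-change groups split `delta` at log2(1.25) and
log2(0.75) (boundaries inclusive to the middle group).

## Metaplots and boundary contrast

`compute_matrix` samples the z track over each region body rescaled to
`body_bins` columns (midpoint sampling) plus fixed-width flanks at
native bin resolution; regions shorter than one body bin are dropped
and counted. `summarize_matrix` reports per-column means with 95% CI
half-widths `1.96 · sd / √n` using the **sample** SD (ddof = 1): rows
(0,0) and (2,2) give mean 1 and half-width 1.96. `boundary_contrast`
measures, for each region edge, mean(outside window) − mean(inside
window) over `w` bp (sign flipped for repressive marks), skipping edges
whose windows leave the chromosome.

## Region-set association

`windowed_peak_coverage` counts covered bp of the merged region
footprint in genome-tiling windows (default 50 kb); profiles are
compared by Pearson correlation. `permutation_overlap_test` uses the
statistic *number of query regions overlapping ≥ 1 bp of the target
footprint*; the null re-places each query region uniformly at random
with its length preserved, choosing the chromosome with probability
proportional to placeable length `L − w + 1`. With
`non_overlapping=True`, colliding placements are rejected and the whole
permutation redrawn. The p-value is `(1 + #tail) / (n_perm + 1)` on the
tail selected by the sign of (observed − null mean), and
`z = (obs − null mean) / null sd`. For a single query of width L
against a single target of width M on a chromosome of length G the
null mean is exactly `(M + L − 1) / (G − L + 1)`, which the tests
verify by Monte Carlo.

The adaptive tail choice makes the realised type-I error
regime-dependent: it is conservative when expected overlaps are sparse
(heavy ties at small counts) and exceeds 0.05 (toward ~0.10) when the
null becomes effectively continuous. Calibration studies in the
acceptance suite therefore use a moderate-overlap design (expected
overlap ≈ 4) where the empirical type-I error sits in [0.03, 0.07] and
the normal approximation for z is accurate. `rank_associations` screens
a library, ranking each target by the better of its correlation rank
and permutation-z rank, with per-target independent RNG substreams
spawned from one seed.

## Repeat expression

Reads may match several loci. Policy `all` adds one count to every
matched locus (so a read matching 4 copies contributes 4 locus counts);
`unique` counts only single-locus reads; `all` dominates `unique`
element-wise, and the `all`-policy grand total equals the total number
of (read, matched locus) pairs exactly. Transcriptome fractions are
computed on *distinct* placed reads against whole-transcriptome mapped
totals, so they lie in [0, 1]. Loci with < `min_count` reads in every
sample are silent and excluded from testing. Family/class
over-representation among up (or down) loci uses the hypergeometric
upper tail with the expressed loci as the universe (k = 5 of K = 5 in a
draw of n = 5 from N = 10 gives p = 1/252), BH-adjusted across groups
at each level; groups with K < 5 are flagged low-power. Each
differential locus is joined to the overlapping differential mark
region with the largest |delta| to correlate RNA and mark fold changes.

## Synthetic data and the noise model

The generator plants, on a 3 × 2 Mb genome with arm/center
compartments: 30 constitutive domains (20–50 kb, 4-fold enriched,
arm-biased), 20 ASRRs (5–15 kb, 1.0-fold young / 2.5-fold old,
center-biased), 150 background regions, fragmented peak calls whose
intra-domain gaps are 0.6–4.4 kb (all mergeable), per-sample mark /
H3-control / active-mark tracks with a shared smooth mappability
baseline, old-age active-mark intrusion at a random half of domain
edges, and six repeat families including a 60-copy SINE-like family
(CELE45) with 4-fold planted induction and 4-way mapping ambiguity.

Counts are **marginally negative binomial** (mean μ, dispersion φ,
variance μ + φμ²) via a gamma–Poisson hierarchy in which the gamma
factor — representing biological, chromatin-prep-level variation — is
shared between the mark IP and its paired H3 control of the same
replicate. This is the property that makes H3 normalisation effective
in the assay being emulated: the shared factor cancels in the
mark/control ratio, leaving Poisson-level noise at the contrast stage
while each individual sample remains NB-dispersed. Modelling the
samples as fully independent NB would leave the biological variance in
the ratio and make two replicates insufficient for reliable detection
of 2.5-fold changes at depth 200 — at odds with the paired design the
package targets.

## Numerics and determinism

All randomness flows from integer seeds through
`numpy.random.default_rng([seed, stage])` substreams, one stage tag per
simulation phase, so adding a stage never perturbs another. Library
screens spawn per-target child seeds from one `SeedSequence`. TSV
floats are written with `%.10g`, bedGraph with `%.6g` (consecutive
equal-value bins run-length collapsed), JSON with sorted keys —
repeated runs of a workflow are byte-identical, which the test suite
asserts. BH adjustment uses `statsmodels`; KS, hypergeometric, Pearson
and t distributions use `scipy`. Classical (Torgerson) MDS is computed
directly by double-centering the squared-distance matrix and
eigendecomposition, with a deterministic sign convention.

## Limitations

- Two replicates per age bound the attainable variance estimates; the
  moderated t relies on the pooled prior, and with `d0 = ∞` on
  well-behaved data it effectively assumes a common variance.
- The permutation test's adaptive one-tail p-value is not uniformly
  calibrated across density regimes (see above); treat its z as the
  primary effect measure when comparing across screens.
- Windowed profile correlations at 50 kb measure territory sharing,
  not base-pair-level overlap.
- Correlations on small paired sets (tens of loci) have sampling SD
  ≈ 1/√(n−1) ≈ 0.2; single-dataset r values of that order are not
  evidence of coupling either way.
- The generator's truth-based evaluations (sensitivity, FDR, domain
  recovery) quantify behaviour under its own noise model; real data
  violate it in ways the synthetic benchmark cannot capture (mappability
  artefacts, copy-number variation, incomplete H3 occupancy).
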