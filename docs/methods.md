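# Methods

This note documents the statistical model behind Ohm, the estimators it
implements, the synthetic library generator used for validation, and the
numerical choices that are not forced by the definitions.

## Setting and vocabulary

A haplotype-resolved Hi-C library consists of read pairs mapped to a diploid
genome in which the two parental haplotypes are distinguished by sequence
variants (SNVs). Each read side carries a haplotype call — maternal (`M`),
paternal (`P`) or unassigned (`.`) — supported by some number of covered SNVs,
possibly with mismatches against the called haplotype. Pairs are classified
as:

- **cis** — same chromosome, same haplotype on both sides;
- **trans-homolog** — same chromosome, different haplotypes (contacts between
  the two homologous copies; the signal of homolog pairing);
- **trans-heterolog** — different chromosomes;
- **unassigned** — any side without a haplotype call.

Phasing stringency presets restrict to pairs with at least `min_snv` SNVs per
side and at most `max_mismatch` mismatches: `snv1` = (≥1, any), `snv2-strict`
= (≥2, 0), `snv3-strict` = (≥3, 0).

**P(s)** is the contact frequency versus genomic separation: the number of
same-chromosome pairs whose 5′-position distance falls in a separation bin,
divided by the number of possible locus pairs at those separations. Bins are
geometric with 8 per decade by default. The denominator counts base-pair
resolution locus pairs, `Σ_chrom Σ_s (L − s)` over integer separations in the
bin (closed-form arithmetic series). Base-pair resolution is the only
parameter-free choice; because every downstream statistic is a ratio of
curves on the same grid, the resolution convention cancels.

## Byproduct fractions

Hi-C libraries contain three non-contact byproducts with diagnostic read
orientations: dangling ends (unligated fragments, inward-pointing reads at
~100–1000 bp), self-circles (self-ligated fragments, outward at ~1–10 kb) and
hairpins (same-strand pairs at < 500 bp). True contacts are
orientation-symmetric, so the same-strand ("tandem") P(s) curve, which pools
the two of the four orientation combinations unaffected by these artifacts,
serves as a baseline: the per-combination true curve is taken to equal half
the tandem curve above 1 kb and to be constant below 1 kb (at its 1-kb value).
Each byproduct fraction is the clamped excess of its orientation curve over
the baseline, summed (as counts) over its separation window and divided by
the library size. These are upper estimates: on byproduct-free libraries the
excesses converge to zero with depth.

## Homolog misassignment (HM)

With per-pair misassignment probability `p` (per side `p/2`), the observed
class-resolved curves are a symmetric two-component mixture of the true ones:

    obs_hom(s) = (1 − p) · true_hom(s) + p · true_cis(s)
    obs_cis(s) = (1 − p) · true_cis(s) + p · true_hom(s)

**Estimation.** Dangling ends make inward cis pairs at 300–600 bp orders of
magnitude more abundant than any true trans-homolog contact at those
separations; an inward "trans-homolog" pair there is almost surely a
misassigned cis pair. The HM probability is therefore estimated — as an upper
bound — by the geometric mean, over the separation bins intersecting
300–600 bp, of the inward trans-homolog to inward cis frequency ratio. Bins
with zero observed trans-homolog pairs contribute a pseudo-count of 0.5 pairs
(configurable) instead of −∞; the geometric mean weights bins equally. A zero
cis frequency in the range is an error (the signature is absent). The
estimate decreases under stricter phasing stringency when misassignment is
driven by per-SNV errors.

**Contamination and correction.** The fraction of observed trans-homolog
contacts that are misassigned cis is `p · P_cis(s) / P_hom_obs(s)`, clamped
to [0, 1]. The 2×2 mixture is inverted exactly per bin for any `p ≠ 0.5`
(where it is singular); the forward-then-inverse round trip is exact algebra.

**No-pairing null.** Under zero homolog pairing, the expected observed
trans-homolog frequency is the average cross-parent trans-heterolog contact
frequency plus `p · P_cis(s)`. The cross-parent heterolog scalar counts only
maternal-versus-paternal heterolog pairs with a doubled locus-pair
denominator, putting it on the same per-haplotype-pair scale as the
trans-homolog P(s). Comparisons report per-bin Poisson z-scores (only where
the expected count reaches 10, below which the normal approximation fails)
and the observed/null ratio.

## Binned matrices

Classified contacts are aggregated into sparse symmetric matrices per
component — cis-maternal, cis-paternal, trans-homolog (pooling (Mᵢ, Pⱼ) with
(Pᵢ, Mⱼ); `--no-pool` keeps them separate) and trans-heterolog — over a
uniform bin table (defaults 1 kb and 4 kb). Cis and trans-homolog pairs below
3 kb separation are excluded (dominated by unligated/self-ligated fragments);
trans-heterolog pairs are unaffected.

**Filtering.** Bins whose log coverage (marginal of the combined map) falls
more than 7 median absolute deviations below the median log coverage are
masked ("MADmax"); zero-coverage bins are always masked. Log space makes the
mask invariant under global count rescaling.

**Balancing.** Iterative correction finds multiplicative per-bin weights such
that every unmasked marginal equals 1.0; convergence is declared when the
variance of the rescaled marginals drops below `tol` (default 10⁻⁶; tighter
tolerances are supported and used in validation against a dense Sinkhorn
oracle). Balancing is per component. The trans-heterolog component is not
balanced by default: it only connects different chromosomes, so unit marginals
on all bins are infeasible whenever chromosomes contain different numbers of
unmasked bins. A joint mode balances the combined map with one shared weight
vector. Balanced matrices are invariant under uniform count rescaling
(weights scale by the inverse square root).

**Observed/expected.** Each intra-chromosomal diagonal of a balanced map is
divided by its chromosome-wide mean over unmasked bin pairs, making every
diagonal mean 1 exactly.

Matrices are written as cooler-layout HDF5 containers and/or plain COO TSV.

## Pairing score, insulation, boundaries

**Pairing score.** `PS(i) = log2` of the mean balanced trans-homolog contact
frequency over all bin pairs `(m, n)` with `m, n ∈ [i−W, i+W]` (default
W = 3 at 4-kb bins, a 7×7 window including the diagonal pairs). Masked pairs
are excluded from the mean; the score is NaN where more than half the window
pairs are masked. Windows are truncated at chromosome ends (a strict mode
reports NaN instead).

**Insulation.** The score at bin *i* sums balanced contacts between
`a ∈ [i−w, i−1]` and `b ∈ [i+1, i+w]` (default window 40 kb), rescaled to the
full pair count when part of the window is masked, divided by the
genome-wide median (so the un-logged track has median 1 exactly) and log2
transformed. Incomplete windows at chromosome ends are NaN.

**Boundary calling.** Minima of the insulation track are detected with the
alternating-extrema "peakdet" algorithm with delta equal to the prominence
cutoff; the prominence of a minimum is the smaller of the rises to its
adjacent detected maxima. Minima below the cutoff, or adjacent (within one
bin) to a masked/NaN bin, are discarded. Calls are invariant under adding a
constant to the track. The cutoff is an explicit parameter (default 0.3 for
haplotype-resolved maps); no automatic bimodality-based selection is
performed.

**Boundary overlap.** A boundary of set A overlaps if set B has a boundary
within ±4 bins (16 kb at 4-kb bins) on the same chromosome — tolerance-window
membership, not bijective matching. Reports the percentage of A in B, B in A
and their mean. The null draws equally-sized uniform random subsets of the
visible (unmasked) bins, repeats 10 times, and compares the observed overlap
to the replicate distribution with a one-sample two-sided t-test.

## Track correlations

External signals are summarized onto 10-kb bins: peak sets as the fraction of
the bin covered after resizing each peak to 1 kb around its center,
quantitative tracks as the coverage-weighted mean. Correlations are Spearman
(mid-rank ties); the partial Spearman ranks all three variables and applies
the first-order partial-Pearson formula with a t-approximation on n − 3
degrees of freedom. Genomic autocorrelation is controlled by permuting 200-kb
blocks of bins within chromosomes (preserving within-block order and the
value multiset) rather than single bins. Quartile stratification partitions
complete bins by mid-rank with stable tie order (group sizes within one).
Mood's median test is a Pearson chi-square on counts above/below the pooled
grand median, ties counted below, no continuity correction. 2-D distributions
are summarized by the sample bivariate Gaussian and its Mahalanobis-distance-2
ellipse.

## Synthetic library generator

The generator emulates a deeply sequenced haplotype-resolved Hi-C experiment
on a hybrid diploid. A genome is two autosomes (defaults 22 and 26 Mb) with
SNVs drawn uniformly at a configurable density (default 5/kb). A library of
`n` read pairs is a multinomial mixture of populations:

- **cis contacts** with `P(s) ∝ s^(−0.8)` above a 1-kb plateau
  (`cis_exponent`, `cis_plateau`), amplitude `cis_amplitude = 6.3×10⁶`
  relative units;
- **trans-homolog contacts**: a flat background at the heterolog level plus an
  exponential pairing kernel `pairing_amplitude · exp(−s / pairing_scale)`
  (defaults 300 and 50 kb) between homologous coordinates;
- **trans-heterolog contacts** at a flat rate `het_level`, with an optional
  Rabl-coalignment kernel on centromere-relative arm coordinates
  (`rabl_amplitude`, off by default);
- **byproducts** at absolute fractions of the library: dangling ends 0.395
  (inward, 100–1000 bp), self-circles 0.003 (outward, 1–10 kb), hairpins
  0.029 (same-strand, 100–500 bp) — all truly cis;
- **haplotype readout**: each side covers the SNVs within a 150-bp read; sides
  covering no SNV are unassigned. Misassignment is injected either directly
  (probability `p_hm/2` per assigned side, default `p_hm = 0.0017`) or via
  independent per-SNV read errors (`snv_error_rate`), under which stricter
  SNV stringencies recover lower HM rates.

Only intensity ratios matter; populations share the non-byproduct remainder
of the library proportionally to their integrated intensity masses (computed
on a log grid by trapezoidal quadrature). Separations are drawn by inverse
CDF on the same grid. Every emitted pair carries a ground-truth sidecar row:
true class, true haplotypes, and per-side misassignment flags. Generation is
fully deterministic given the model seed.

## Numerical choices and limitations

- Bin-resolution choices (geometric P(s) grid, bp-resolution denominators)
  cancel in all downstream ratios; they are conventions, not assumptions.
- The HM estimator is an upper bound: any true short-range trans-homolog
  signal inflates it. On simulated libraries with the default pairing kernel
  the inflation at 300–600 bp is negligible relative to the dangling-end cis
  signal.
- The mixture inversion is exact only bin-wise on frequencies; it does not
  propagate count noise (corrected curves can be slightly negative where the
  true trans-homolog frequency is near zero).
- The Rabl curve's denominator averages the two arm-rescaling directions
  while each observed pair is rescaled side-2-into-side-1; the conventions
  differ near the end of the shorter arm. Contrasts between libraries on the
  same genome are unaffected.
- Iterative correction on bipartite (trans-heterolog) maps is infeasible in
  general; see above.
- The insulation score reports NaN where the crossing sum is exactly zero
  (log2 of zero); with balanced real-valued maps this occurs only on empty
  windows.
- Statistical calibration (Mood's test and Spearman p-values uniform under
  the null) is verified by simulation in the test suite.
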