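# Methods

## Eigengene decomposition

The expression matrix *D* (genes × ordered timepoints, nonnegative,
finite) is factored by a thin SVD, `numpy.linalg.svd`. The
decomposition requires at least as many genes as timepoints so that the
patterns span time space; *r* always equals the number of timepoints
and zero singular values are retained, so a 12-bin series always yields
12 eigengenes.

Two preprocessing options exist, both off by default. `transform="log1p"`
compresses the dynamic range of abundance data; `center=True` subtracts
each gene's mean across timepoints. The default is *no* centering:
with raw nonnegative abundances the leading eigengene is the
approximately constant baseline-expression pattern, which is itself an
informative feature of a staged series. Centering removes that
direction and focuses the spectrum on temporal change.

**Eigenexpression fractions** divide each singular value by the sum of
singular values — linearly, not squared. Squaring (a variance
convention) would concentrate the spectrum further; the linear form is
used consistently here for the fractions, the cumulative fraction and
the entropy.

**Shannon entropy** is the normalised form d = −(1/ln n)·Σ eᵢ ln eᵢ
with 0·ln 0 := 0, natural logarithm, clipped into [0, 1] against
rounding. The endpoints are exact: a degenerate spectrum gives d = 0,
a uniform one d = 1. Fractions must sum to 1 within 1e-8 or the input
is rejected.

**Sign orientation.** SVD signs are arbitrary, so each eigengene is
oriented to make its largest-magnitude timepoint positive, and the
matching *U* column is flipped in tandem; the applied signs are kept in
`orientation_signs`. Gene ranking ("columns of *U* sorted in
descending order") uses signed loadings after this orientation; ties
are broken lexicographically by gene ID so output is deterministic.

## Hypergeometric enrichment

The upper-tail probability P(X ≥ k) is summed over i = k … min(K, m);
terms with i > K or m − i > M − K lie outside the support and are zero.
Each term is evaluated as log-binomials via `scipy.special.gammaln` and
the sum via `logsumexp`, so p ≈ 10⁻²⁰ carries full relative precision.
When the tail covers the whole support the function returns exactly 1,
and p is clamped into (0, 1]. Selections containing genes outside the
declared universe are filtered with a warning before m and k are
counted. Raw p-values are reported; no multiple-testing correction is
applied by default because a single catalog per pattern is the primary
use (a Bonferroni/BH layer can be added downstream, and the metabolite
summariser exposes a BH flag).

## Metabolite time-course statistics

Order of operations: internal-standard normalization → baseline-relative
scaling → per-bin tests. Because the baseline rescaling is one uniform
factor per metabolite, the Welch p-values are identical whether computed
on normalized or rescaled values; the rescaled scale is used for the
reported medians/quartiles.

*Missing vs zero.* Peak areas below detection are missing (NaN) and are
excluded from quartiles and tests; a measured zero is data. A sample
whose internal standard is missing or ≤ 0 is treated as a failed
injection and dropped with a warning.

*Baseline-undetectable metabolites.* If the baseline statistic is 0 the
fold scale is undefined. Rather than inventing a pseudo-count, the
metabolite keeps its normalized values and is flagged
`"undetectable at baseline"`; its later-bin tests still run on the
normalized scale.

*Tests.* Welch's unpaired two-sample t-test (Welch–Satterthwaite df,
two-sided) per metabolite × bin against baseline, delegated to
`scipy.stats.ttest_ind(equal_var=False)` with explicit handling of the
degenerate zero-variance cases (equal means → p = 1 by convention;
unequal means → rejected as undefined). Samples are independent
collections, so only unpaired tests are offered. Store assays use the
pooled-variance Student t-test at α = 0.05 with baseline-relative means
and SEM, matching how bulk TAG/glycogen/protein assays are usually
reported.

## Synthetic-data generator

The generator emulates the *structure* of a staged embryonic study, not
its biology: it exists so each analysis stage has a ground truth.

*Expression.* The matrix is `baseline_offset + Σₚ weightₚ · loadingsₚ ⊗
patternₚ + N(0, noise_sd²)`, clipped at zero. Default patterns mirror a
staged series: a constant baseline program, a sigmoidal mid-series
step-up, and a U-shaped dip-and-recover program. Shapes are
orthonormalized by QR before mixing — a deliberate idealization that
makes each planted component identifiable as an SVD triplet. Gene
membership of the non-constant patterns is disjoint, keeping their
loading vectors orthogonal; the constant pattern spans all genes with
lognormal(0, 0.5) loadings, so its overlap with the other programs
introduces only a small, quantifiable rotation. Defaults (weights
30/12/8, member fractions 1.0/0.2/0.1, noise_sd 0.25, offset 2) put the
weakest planted pattern at signal-to-noise ≥ 10, where recovery is
demanded; the realized per-pattern SNR, weightₚ·‖loadingsₚ‖ /
(noise_sd·√G), is recorded in the truth object.

*Annotations.* K catalog genes are drawn without replacement with
sampling weight `ratio` on the m top-loading genes of a target pattern,
giving expected top-m overlap K·m·ratio/(m·ratio + M − m);
`ratio_for_expected_overlap` inverts this, and the realized ratio is
recorded. The classic operating point (M = 17,000, K = 1,228, m = 500,
expected k = 99) corresponds to ratio ≈ 2.9.

*Metabolome.* Peak area = base_area · trajectory(t) · lognormal(0,
noise_sd) · injection factor, with the internal-standard column carrying
standard_area · the same injection factor, so normalization cancels the
factor exactly — a property tested as an exact round trip. Defaults
(12 bins × 7 replicates, lognormal σ = 0.2 on peaks, σ = 0.3 on
injection drift) approximate the replicate scatter of a targeted GC-MS
panel. Trajectory presets span the magnitudes such surveys report: a
10-fold riser from the quarter-point, a 98% step drop past the
midpoint, a 100-fold riser, an early 10-fold dip with recovery, and a
flat control.

*What the generator does not emulate:* count noise at the read level,
gene–gene correlation beyond the planted patterns, retention-time or
batch artifacts beyond a scalar injection factor, and metabolite
identification ambiguity. Passing recovery tests therefore demonstrates
the statistical machinery under the stated noise models, not robustness
to every artifact of real data.

## Numerical choices and edge cases

- Fractions must sum to 1 within 1e-8; reconstruction and
  orthonormality are tested at 1e-8; the tail sum is tested against an
  exact rational oracle at 12 significant figures.
- All randomness flows through `numpy.random.default_rng` (PCG64) with
  explicit seeds; generator outputs and pipeline re-runs are
  byte-identical under a fixed seed and configuration.
- Problem sizes in the test suite are the package's own choices: the
  pattern-recovery fixture uses 5,000 genes (SNR is size-invariant by
  construction), the eigengene-count check runs at the full 17,000, the
  null calibrations use 1,000 enrichment replicates, 10,000 Welch
  simulations and 500 flat metabolites.

## Known limitations

- The constant planted pattern cannot be scored by Pearson correlation
  (undefined against a constant vector); cosine similarity is used for
  it, Pearson for the others.
- Enrichment p-values are exact but conditional on the user-supplied
  universe M; with real annotation data M depends on upstream gene-ID
  reconciliation, which this package does not attempt.
- The mHG/ranked-list scanning style of enrichment (threshold-free) is
  out of scope; the test takes a fixed top-N selection.
- Box-plot figures and eigengene line plots are intentionally simple;
  figures are excluded from byte-exactness guarantees (data files are
  byte-stable, rendered images need not be).
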