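# Methods

## Scope and data model

The unit of analysis is a *grey panel*: one reference series (disease
burden, e.g. annual DALYs as a percentage of population) and an ordered
set of comparative series (risk-factor exposures) over the same epochs.
Epochs are treated as equally spaced regardless of their labels — every
grey formula indexes by position $\ell = 1..h$ — and series must be
complete: missing values are rejected rather than imputed, because all
three grade definitions assume a value at every epoch and imputation
would silently manufacture curve shape, which is exactly what the
grades measure.

## Normalization

Series with different units or magnitudes must be made dimensionless
before deviations between them mean anything. Which operator to use is
a genuinely open choice in the grey-systems literature, so it is an
explicit, logged parameter of every run rather than a hard-wired step:

| method | action | requires |
|---|---|---|
| `none` | leave values as-is | — |
| `initial_value` | divide by the first value | nonzero first value |
| `mean_image` | divide by the series mean | nonzero mean |
| `min_max` | affine map onto [0, 1] | non-constant series |

The default is `mean_image`, the classical grey "averaging operator":
it preserves relative within-series variation, is scale-free, and does
not privilege the (possibly noisy) first epoch the way `initial_value`
does. Each series is normalized independently; a panel-global variant
was considered and rejected because it would let one large-magnitude
factor set the scale for all others. Normalization applies to the
reference and all comparatives with the same method; `mean_image` and
`min_max` are idempotent to floating tolerance.

Because the default is a convention, grade *values* depend on it even
though grade *orderings* are usually stable; published grade columns
computed from an unavailable extract under an unstated operator are
therefore treated as inputs, never as recomputation targets.

## The three grades

**Deng's grade.** The point coefficient contrasts each epoch's absolute
deviation against the extreme deviations, softened by the
distinguishing coefficient $\zeta$ (default 0.5; smaller values sharpen
contrast, values near 1 flatten it). The min/max extremes are taken
panel-wide (over all comparatives and epochs — the classical reading of
the double subscripts) by default; a `per_pair` scope is offered for
two-series use. When every deviation is zero the coefficient is 0/0;
it is defined as 1 — the limit, the grey-systems convention, and the
only value under which identity scores a perfect grade.

**Absolute grade.** Zero-start images remove level, and their signed
integrals are discretized by the trapezoid rule on unit spacing, which
reproduces the classical discrete incidence quantity
$\sum_{\ell=2}^{h-1} x^0(\ell) + x^0(h)/2$ exactly — the standard
discretization in the grey-incidence literature. The grade is invariant
under adding a constant to either series, and equals 1 iff the
difference of zero-start images integrates to zero.

**Second synthetic grade.** A convex blend, $\vartheta = 0.5$ by
default so neither notion of proximity is privileged. It is monotone in
$\vartheta$ toward whichever component is larger and is always
sandwiched between the two.

Grades are computed on the normalized panel by default (raw-panel
grading is available by passing `normalization="none"`). Internally all
values are kept at full precision; display rounds to 4 decimals.

## Ranking, Pearson cross-check, Hurwicz

Factors are ranked per metric in strictly descending grade order; exact
ties are broken lexicographically by label and reported in the output
metadata so they cannot pass silently. Pearson's $r$ is computed on the
same normalized series the grades see, as a conventional check that the
grey ordering is not an artifact of the method — its values are not
comparable to grades, only its induced ordering is used.

The Hurwicz criterion scores each disease (alternative) by
$\alpha \cdot \text{best payoff} + (1-\alpha) \cdot \text{worst payoff}$
over its row of second-synthetic grades, $\alpha = 0.8$ by default. The
criterion is exposed with an explicit `objective` parameter (default
`minimize`, matching the displayed decision rule): with payoffs that
are association grades, the minimizing alternative is the one whose
*worst* factor association is still comparatively strong — often read
as the disease more broadly affected by the factor set. Both directions
are computed and reported; the interpretation is left to the analyst.

## Synthetic panels and what they do (not) show

The generator emulates the intended input: short annual series (default
10 epochs, 2010–2019) at percent-of-population scale.

* reference: `base_level + trend_slope·t + N(0, noise_sd)`, floored at
  1e-6 to keep percent semantics. Defaults `base_level=2.0`,
  `trend_slope=0.05`, `noise_sd=0.02` give a burden around 2% with a
  gentle upward trend and mild year-to-year jitter.
* factor $k$: the reference plus a level offset plus
  `distortion_k · (bump + N(0, noise_sd))`, floored likewise.

The *bump* is a smooth, zero-mean, unit-RMS low-order polynomial drawn
once per panel and shared by all factors. Sharing the direction of
distortion is deliberate: it guarantees that a larger distortion level
moves a factor strictly farther from the reference in both the
pointwise (Deng) and integral (absolute) sense, so the planted ordering
is well defined — with independent per-factor shapes, a heavily
distorted factor whose shape happens to integrate to nearly zero would
still score a high absolute grade and the noiseless ordering would not
be recoverable even in principle. Level offsets are drawn uniformly in
±5% of `base_level`: large enough to exercise the absolute grade's
shift invariance, small enough that mean normalization leaves the
planted ordering intact (at ±5% the offset-induced shape deviation is
an order of magnitude below the smallest nonzero distortion gap).

The default distortion spectrum (0, 0.1, 0.2, 0.4, 0.8, 1.6) is a
geometric spread: adjacent factors differ by a factor of two in
distance from the reference, i.e. a clearly separated planted order.
All randomness flows through one `numpy` generator seeded from a single
integer; replicate streams are spawned via `SeedSequence`, so every
experiment is exactly reproducible.

What passing recovery tests shows: the pipeline reliably recovers a
*planted, well-separated* similarity ordering from 10-epoch panels at
small noise, and degrades gracefully (mean Kendall tau) as noise grows.
What it does not show: performance on real GBD-like data, whose series
are serially correlated, near-collinear across factors, subject to
revision artifacts, and not generated by any shared-shape mechanism.
No attempt is made to calibrate the generator to real magnitudes.

## Numerical choices and degenerate inputs

* Deng 0/0 (identical panel) → coefficient 1, see above.
* `series_integral` requires an exact zero first value — it operates on
  zero-start images by contract, not on raw series.
* Zero-divisor normalizations and constant-series `min_max` raise
  errors naming the offending series; they are never silently skipped.
* Pearson requires ≥3 epochs and non-constant series; constant input is
  an error, not NaN.
* Hurwicz and ranking ties break toward the earlier alternative /
  lexicographically smaller label, always with a tie flag.
* Grades are validated into $(0, 1]$ before blending.

## Problem sizes used in checks

Oracle-equivalence checks compare the vectorized engines against
independent loop-based transcriptions on 500 randomized pairs of
lengths 2–50 under both extremes scopes (agreement to 1e-12). Ranking
recovery uses the default study-like configuration with 200 replicates,
and the noise-degradation grid (noise_sd 0, 0.05, 0.25, 1.0, 4.0) uses
150 replicates per level; the monotonicity check allows a 0.01
Monte-Carlo slack for ties between saturated (tau ≈ 1) grid points.

## Known limitations

* Only the three implemented grades; no relative/similarity/closeness
  incidence variants, no grey forecasting, and no other decision
  criteria (maximin, Savage regret, Laplace, TOPSIS).
* Point grades only — no uncertainty intervals; with ~10 epochs any
  resampling interval would be close to vacuous.
* The published correlation-index column bundled with the reference
  tables is used only for the ordering it induces; its scale is not a
  product-moment correlation and is not reproduced.
* Grade values (not usually orderings) depend on the normalization
  convention; cross-study comparison of raw grade magnitudes is not
  meaningful without agreeing on the operator.
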