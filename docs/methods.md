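# Methods

This note documents the models, conventions and numerical choices behind
`fruitsignals`, the points where the methodology was genuinely open and
how this package resolved them, and what the synthetic-data tests do and
do not demonstrate about real data.

## Trait indices

**Surface area.** Fruit surface area uses the Knud-Thomsen ellipsoid
approximation with exponent p = 1.6075, whose worst-case relative error
is ≈1.06% over all axis ratios (the test suite verifies <1.1% against a
numeric surface integral). Caliper dimensions are interpreted as full
extents (diameters) and halved to semi-axes by default, since calipers
measure full extents; `dims_are="semi_axes"` overrides this. Whether the
packaged table's printed SA:W column used full or semi-axes cannot be
verified from the table itself (raw dimensions are not published); the
flag exists for exactly that reason.

**VOC index.** `log10((voc_sum − Σ blank_peaks) / area)`. Blank
subtraction is a scalar sum of named contamination-peak areas;
chromatogram-level peak matching is out of scope. A non-positive net VOC
raises an error naming the species rather than propagating a NaN.

**Brightness normalization.** The minimum reflectance over 400–700 nm is
subtracted from the whole spectrum (negatives outside the visible range
clip to zero). This corrects additive spectrometer drift, is idempotent,
and makes downstream fits invariant to a constant offset added to a raw
spectrum.

**Band shares.** Bands are half-open — UV [300, 400), blue [400, 500),
green [500, 600), red [600, 700] — so every wavelength contributes to
exactly one band; the published band edges overlap on paper and this is
the tie-break. Shares are discrete sums over measured grid wavelengths
(not trapezoid integrals) divided by the visible-range (400–700 nm)
total, as percentages. Blue+green+red therefore sum to exactly 100,
while UV is not bounded by the others because its numerator lies outside
the denominator. λmax and peak brightness are restricted to 400–700 nm.

## Correlation screen

Pearson r with the exact two-tailed t reference (df = n−2), no multiple-
testing correction (matching the original analysis). Two default
transforms matter:

- VOC and SA:W enter as log10 (the analysis scale of the regression).
- The four band percentages are **jointly renormalized** by their sum
  (uv+blue+green+red), i.e. converted from shares of visible reflectance
  to shares of total 300–700 nm reflectance.

The renormalization is the package's resolution of an underdocumented
step: recomputing the published correlation table from the packaged
trait table reproduces every printed cell to 2 dp **only** under this
transform (e.g. UV–blue prints 0.43; the raw printed columns give 0.59).
Both behaviours are available via `renormalize_bands`; the default
reproduces the published table and the test suite records the check.

## Spectral spline regression

**Basis convention.** The five spectral predictors are weighted sums of
the proportion-scaled spectrum with weights from a natural cubic spline
with knots at 350, 410, 470, 530, 590 nm and a 650 nm referent. A
natural-spline space on K knots has dimension K, so five knots alone
cannot yield five non-constant, referent-centered columns; this package
includes the referent as the sixth, outermost knot and re-centers every
basis function to vanish at 650 nm. That leaves exactly five columns,
makes 650 nm the zero-effect reference wavelength (protecting against
the collinearity induced by spectra summing to 100%), and implies linear
(natural) extrapolation below 350 and above 650 nm over the 300–700 nm
grid. The constructor refuses any configuration that does not produce
exactly five full-rank columns.

**Scale.** Spectra are proportion-scaled to sum to 100 over 400–700 nm
before the weighted sums, so all coefficients are "log10 VOC per percent
reflectance" — the same unit as the band shares. Predictor evaluation is
strictly linear in the supplied values and refuses a wavelength grid
that does not match the basis grid (no silent interpolation).

**Fit.** The observation unit is the species (one spectrum each); OLS of
the VOC index on the five predictors plus log10(SA:W) and an intercept,
fit with statsmodels. The overall spectral effect is the 5-df F test
against the size-only model. A pooled per-wavelength fit is not
attempted: the raw multi-species spectra behind the original pooled
analysis are unpublished, so correctness is established by synthetic-
data recovery instead.

**Band effects.** The cumulative coefficient of a band is c'β with c the
unweighted mean basis row over the band's grid wavelengths (a `sum`
aggregation is exposed; "cumulative" is otherwise unspecified), variance
c'Σc by the delta method, p from the residual-df t reference. The
delta-method variance is exact here because the contrast is linear; the
test suite confirms it against a Monte-Carlo oracle.

**Known attenuation.** A band effect estimates the band average of the
spline-smoothed effect curve. When the true effect is a sharp box over
one 100 nm band — as in the synthetic generator, where VOC responds
linearly to the blue share — the five-column spline cannot represent the
discontinuity and the band-averaged estimate is attenuated: across bump
widths 20–120 nm the population attenuation factor stays near 0.8–0.9
(the plain least-squares projection of the blue indicator onto the basis
span has band mean 0.84). The tests therefore check that the recovered
blue effect is negative, strongly significant, and within the documented
attenuation range of the injected value, and that the correctly-
specified size coefficient is recovered without bias. Users comparing a
band effect against an external per-percent effect size should bear
this smoothing attenuation in mind; it is a property of the method, not
of the implementation.

## Phylogenetic signal

**Framework tree.** Orders form a root polytomy, families nest in
orders, genera (first token of the species label) in families, species
as tips; unit branch lengths, since a classification carries no
molecular lengths (a newick tree with real lengths can be supplied
instead). Species with unknown family/order attach directly to the root
polytomy. Single-child chains are kept as-is; polytomies are never
arbitrarily resolved.

**Continuous parsimony.** Minimum total absolute change under linear
(Farris) parsimony, computed exactly by propagating convex piecewise-
linear cost functions from tips to root; after the parent-edge
relaxation each subtree is summarized by its optimal closed interval, so
polytomies are handled natively and branch lengths are ignored (steps
are in trait units). Verified against an exact L1 linear program on
random trees to 1e-9.

**CI and RI.** CI = m/s with m the trait range (minimum conceivable
steps) and s the observed steps; RI = (g−s)/(g−m) with g the worst-case
steps. For continuous characters g is defined here as the star-tree cost
Σ|xᵢ − median(x)| — the natural continuous analogue of the discrete
worst case. This choice is stated prominently because published RI
values depend on it and parsimony software does not document its
convention. A constant trait raises (CI undefined); when g = m (e.g.
two tips) RI is returned as NaN.

**Blomberg's K.** The observed MSE₀/MSE ratio about the GLS
(phylogenetically corrected) mean, standardized by its Brownian
expectation `(tr(C) − n/1'C⁻¹1)/(n−1)`. Significance by tip
randomization (default 1000 permutations, seeded): p is the proportion
of permutations with phylogenetic MSE ≤ observed, with the +1
correction. K matches R phytools to 6+ digits in a cross-check test.

**Pagel's λ.** Off-diagonal entries of the Brownian covariance are
scaled by λ ∈ [0, 1]; the rate and root state are profiled analytically,
leaving a bounded scalar likelihood search (tolerance 1e-8, endpoints
checked explicitly so boundary optima are exact). The p-value refers
2ΔlogL to χ²₁. Because the null λ = 0 lies on the parameter boundary the
statistic is asymptotically a ½χ²₀+½χ²₁ mixture, so this reference is
conservative (null p-values pile up at 1 rather than being uniform);
the calibration tests assert validity (type-I error ≤ nominal), not
uniformity. The K permutation p, by contrast, is uniform under its null
and is tested for uniformity.

K and λ are invariant to affine trait transforms; parsimony steps scale
with the trait, so CI/RI are scale-free.

## Synthetic communities

The generator emulates: smooth single-peak reflectance spectra
(Gaussian bump at a latent hue plus a broad low base bump, multiplied by
mild log-normal noise) on a 300–700 nm grid at 20 nm (56 species × 21
wavelengths ≈ 1176 pooled values, near the field study's 1137 — the
original sampling resolution is unpublished, so the grid is
configurable); ellipsoidal fruits with log-uniform diameter 3.2–85 mm
and near-water density, giving SA:W spanning roughly 70–2000 mm²/g; and
a VOC index generated directly on the log10 analysis scale as
`α + β_blue·blue% + β_saw·log10(SA:W) + N(0, σ)` with defaults
β_blue = −0.04 per percent, β_saw = +0.5 per log10 unit, σ = 0.35 —
effect sizes matching the field community's fitted associations, with
α chosen to centre the VOC index near the field mean of ~0.75. Traits
carry no phylogenetic structure by default (white noise); Brownian and
λ-models on the community tree are available for calibrating the signal
tests, and a rate-1 Yule simulator provides ultrametric trees with
strictly positive branch lengths.

What the generator does **not** emulate: pigment chemistry or radiative
transfer (spectra are generic smooth curves, not anthocyanin/chlorophyll
mixtures), chromatographic noise in VOC sums, within-species variation
(one spectrum per species, as in the field protocol), measurement error
in calipers/weights, or realistic clade-specific trait syndromes.
Passing recovery tests therefore demonstrate that the estimators do what
they claim under the assumed sampling model — not that the field data
satisfy that model.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; identical config + seed reproduces communities, reports
  and permutation p-values byte-identically. Report files embed a
  provenance block (versions, seed, config hash) and contain no
  timestamps.
- Trait tables and spectra are written with 17-significant-digit floats
  and read with round-trip float parsing, so write→read cycles are
  exact.
- Species labels match by exact string comparison; the packaged table
  keeps the published spellings verbatim, including two species pairs
  with identical printed reflectance rows and the printed family/order
  assignments.
- Degenerate inputs fail loudly with the species or variable named:
  constant traits (CI, K, λ, Pearson), zero visible reflectance,
  non-positive net VOC, rank-deficient spline designs, grids that do not
  match the basis.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the tested tolerance: 200 replicates on a 50-tip
Yule tree for the K and λ calibrations, 1000 null communities of 56
species for the F-test size, 10⁴ draws for the delta-method/Monte-Carlo
comparison, 500-species communities for effect recovery, and 50 random
trees of ≤8 tips for the exact parsimony oracle.
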