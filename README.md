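# fruitsignals

Do fruits trade colour against odour? In communities with both
visually-oriented and olfaction-driven seed dispersers, the fruit
syndrome hypothesis predicts a negative relationship between investment
in chromatic signals and investment in volatile (odour) signals.
`fruitsignals` is a library for testing that prediction in a community
trait table: it quantifies chromatic and olfactory fruit traits, screens
their associations, fits a spline-based spectral regression, and tests
whether any trait is phylogenetically constrained. It ships the
published 56-species Madagascar dry-forest community table as a packaged
dataset and a synthetic-community generator so every stage can be
validated against known ground truth.

It is intended for sensory and community ecologists working with
reflectance spectrometry and VOC (volatile organic compound) sampling of
fruits, and for anyone who wants a tested reference implementation of
the statistics below.

## What it computes

**Trait indices.** Fruit surface area by the Knud-Thomsen ellipsoid
approximation `4π[((ab)^p + (bc)^p + (ac)^p)/3]^(1/p)` with `p = 1.6075`
on caliper semi-axes; the VOC index `log10` of the surface-area-scaled
VOC sum (after optional blank-peak subtraction); brightness-normalized
reflectance spectra (minimum over 400–700 nm set to zero); band shares
for UV (300–400 nm), blue (400–500), green (500–600) and red (600–700)
as percentages of total visible (400–700 nm) reflectance; peak hue
λmax and peak brightness.

**Association screen.** Pearson correlations of the VOC index with each
band share and with log10 surface-area:weight, with exact two-tailed
t-reference p-values (`t = r√(n−2)/√(1−r²)`).

**Spectral spline regression.** Each proportion-scaled spectrum is
collapsed to five predictors — weighted sums with weights from a natural
cubic spline over wavelength (knots 350, 410, 470, 530, 590 nm;
650 nm referent at which all basis functions vanish). OLS of the VOC
index on these plus log10(SA:W); overall spectral effect by the 5-df F
test; per-band cumulative coefficients `c'β` with delta-method variance
`c'Σc`.

**Phylogenetic signal.** A framework tree built from the taxonomy
(orders → families → genera as nested polytomies, unit branch lengths)
or any supplied newick tree; continuous-character linear (Farris)
parsimony steps with consistency index `CI = m/s` and retention index
`RI = (g−s)/(g−m)`; Blomberg's K with a tip-randomization test; maximum-
likelihood Pagel's λ with a likelihood-ratio test.

**Synthetic communities.** Gaussian-bump spectra, ellipsoidal geometry,
log-normal VOC with injectable generating effects
(`voc_index = α + β_blue·blue% + β_saw·log10(SA:W) + ε`), and
white-noise / Brownian / λ-structured traits on Yule or taxonomy trees.

## Worked example

```python
from fruitsignals import correlation_matrix, load_table1

records = load_table1()          # the packaged 56-species community
table = correlation_matrix(records)
res = table.results[("voc_index", "blue")]
print(f"blue vs VOC: r = {res.r:+.2f}, p = {res.p_two_tailed:.3f}")
print(f"size vs VOC: r = {table.results[('voc_index','saw')].r:+.2f}")
```

prints

```
blue vs VOC: r = -0.32, p = 0.017
size vs VOC: r = +0.50
```

the colour–odour trade-off signature: the more a fruit reflects in the
blue band, the lower its odour emission, while smaller fruits (higher
surface-area:weight) emit more VOC per unit surface. The `examples/`
directory has one narrative script per capability:

- `01_published_correlations.py` — the full correlation table with
  significance stars,
- `02_spectral_spline_regression.py` — spline fit and delta-method band
  effects on a community with a known injected blue effect,
- `03_phylogenetic_signal.py` — CI/RI, Blomberg's K and Pagel's λ for
  every trait on the framework tree,
- `04_synthetic_community.py` — generating, inspecting and writing a
  synthetic community.

A thin CLI mirrors the stages
(`fruitsignals simulate|correlate|fit-spline|phylo-signal|run-all`).

## Layout

- `src/fruitsignals/traits.py` — trait indices and spectrum handling
- `src/fruitsignals/correlations.py` — Pearson screen
- `src/fruitsignals/spline.py` — spectral spline regression, band effects
- `src/fruitsignals/phylo.py` — framework tree, parsimony, K, λ
- `src/fruitsignals/synth.py` — synthetic communities
- `src/fruitsignals/io.py`, `pipeline.py`, `cli.py` — files, orchestration
- `src/fruitsignals/data/table1_traits.csv` — the packaged community
- `docs/methods.md` — modelling assumptions, conventions and limitations
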