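"""Multivariate spectral regression of VOC emission on reflectance.

Instead of regressing the VOC index on the four coarse band percentages
(which are strongly inter-correlated), each proportion-scaled spectrum is
collapsed to five predictor variables: weighted sums of its reflectance
values, with weights given by a natural cubic spline basis over wavelength
with knots at 350, 410, 470, 530 and 590 nm.  The 650 nm bandwidth acts as
a fixed referent — every basis function is re-centered to vanish at 650 nm
— which removes the constant function from the basis span and so protects
against the multi-collinearity induced by the spectra summing to 100%.

Basis convention: the referent wavelength is included as the sixth (and
outermost) spline knot, so the natural-spline space has dimension six and
dropping the constant by referent-centering leaves exactly five columns.
The natural (zero second derivative) condition makes the basis linear
below 350 nm and above 650 nm, covering the full 300-700 nm grid by linear
extrapolation.

The fitted model is ordinary least squares of log10 VOC on the five
spectral predictors plus log10 surface-area:weight, and the overall
spectral effect is the 5-df F test against the size-only model.  Per-band
cumulative effects are linear contrasts c'beta (c = mean basis row over
the band's wavelengths) with delta-method variance c' Sigma c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .traits import (
    BANDS,
    Spectrum,
    SpeciesTraitRecord,
    band_mask,
    normalize_brightness,
    visible_mask,
)

__all__ = [
    "SplineBasis",
    "SplineModelFit",
    "BandEffect",
    "CollinearityError",
    "build_basis",
    "proportion_spectrum",
    "spectrum_predictors",
    "fit_model",
    "band_effect",
    "band_effects",
]

DEFAULT_KNOTS: tuple[float, ...] = (350.0, 410.0, 470.0, 530.0, 590.0)
DEFAULT_REFERENT: float = 650.0


class CollinearityError(ValueError):
    """Raised when the regression design matrix is rank deficient."""


def _natural_spline_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (constant excluded) at points *x*.

    Truncated-power construction: columns are ``x`` and, for each interior
    knot k = 1..K-2, ``d_k(x) - d_{K-1}(x)`` with
    ``d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)``.
    The span is the K-dimensional natural-spline space minus constants:
    linear outside the outer knots, C2 everywhere.
    """
    x = np.asarray(x, dtype=float)
    K = knots.size
    xiK = knots[-1]

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - xiK, 0.0, None) ** 3
        return num / (xiK - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineBasis:
    """Referent-centered natural cubic spline basis on a wavelength grid."""

    knots: tuple[float, ...]
    referent: float
    boundary: tuple[float, float]
    grid: np.ndarray
    basis_matrix: np.ndarray  # len(grid) x n_columns

    @property
    def n_columns(self) -> int:
        return self.basis_matrix.shape[1]

    def evaluate(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Evaluate the centered basis at arbitrary wavelengths."""
        all_knots = np.asarray(sorted(set(self.knots) | {self.referent}))
        raw = _natural_spline_columns(np.asarray(wavelengths, float), all_knots)
        at_ref = _natural_spline_columns(np.asarray([self.referent]), all_knots)
        return raw - at_ref


def build_basis(
    knots: Sequence[float] = DEFAULT_KNOTS,
    referent: float = DEFAULT_REFERENT,
    grid: Sequence[float] | None = None,
    boundary: Sequence[float] | None = None,
) -> SplineBasis:
    """Construct the five-column spectral spline basis on a grid.

    ``knots`` are the spline knots; ``referent`` is appended as the
    outermost knot and every column is re-centered to vanish there.  Extra
    ``boundary`` knots may be supplied explicitly, but the constructor
    insists on exactly five resulting columns (the model's dimension), so
    a configuration that changes the column count raises rather than
    silently refitting a different model.
    """
    if grid is None:
        grid = np.arange(300.0, 701.0, 20.0)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a nonempty strictly increasing 1-D array")
    knot_set = set(float(k) for k in knots)
    if boundary is not None:
        knot_set |= {float(b) for b in boundary}
    if float(referent) in knot_set:
        raise ValueError(f"referent {referent} nm must be distinct from the knots")
    all_knots = np.asarray(sorted(knot_set | {float(referent)}))
    if np.any(np.diff(all_knots) <= 0):
        raise ValueError("knots must be distinct")
    n_cols = all_knots.size - 1
    if n_cols != 5:
        raise ValueError(
            f"configuration yields {n_cols} basis columns, not the 5 spectral "
            "predictors of the model; adjust knots/boundary explicitly"
        )
    raw = _natural_spline_columns(grid, all_knots)
    at_ref = _natural_spline_columns(np.asarray([float(referent)]), all_knots)
    matrix = raw - at_ref
    if np.linalg.matrix_rank(matrix) < n_cols:
        raise ValueError(
            "basis matrix is rank deficient on this grid; use a denser grid"
        )
    return SplineBasis(
        knots=tuple(sorted(knot_set)),
        referent=float(referent),
        boundary=(float(all_knots[0]), float(all_knots[-1])),
        grid=grid,
        basis_matrix=matrix,
    )


def proportion_spectrum(spectrum: Spectrum, percent: bool = True) -> np.ndarray:
    """Reflectance divided by total visible (400-700 nm) reflectance.

    With ``percent=True`` (default) values are scaled so the visible range
    sums to 100, putting regression coefficients on the same
    per-unit-percent scale as the band indices.
    """
    if not spectrum.normalized:
        spectrum = normalize_brightness(spectrum)
    total = spectrum.visible_total()
    if total <= 0:
        raise ZeroDivisionError(
            f"{spectrum.label}: zero visible reflectance; cannot scale spectrum"
        )
    scale = 100.0 if percent else 1.0
    return scale * spectrum.reflectance / total


def spectrum_predictors(spectrum: Spectrum | np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Collapse a proportion-scaled spectrum to the five spline predictors.

    ``predictor_j = sum_w basis[w, j] * reflectance[w]`` — strictly linear
    in the supplied values (scale them with :func:`proportion_spectrum`
    first).  The spectrum's wavelengths must match the basis grid exactly;
    no silent interpolation.
    """
    if isinstance(spectrum, Spectrum):
        if spectrum.wavelengths.shape != basis.grid.shape or not np.allclose(
            spectrum.wavelengths, basis.grid
        ):
            raise ValueError(
                f"{spectrum.label}: spectrum wavelengths do not match the basis "
                "grid; resample the spectrum explicitly"
            )
        values = spectrum.reflectance
    else:
        values = np.asarray(spectrum, dtype=float)
        if values.shape != (basis.grid.size,):
            raise ValueError(
                f"value vector length {values.size} does not match basis grid "
                f"length {basis.grid.size}"
            )
    return values @ basis.basis_matrix


PREDICTOR_NAMES = ("s1", "s2", "s3", "s4", "s5")


@dataclass(frozen=True)
class SplineModelFit:
    """OLS fit of VOC index on spectral spline predictors + log10 SA:W."""

    coefficients: dict[str, float]  # const, s1..s5, log_saw
    covariance: np.ndarray  # full coefficient covariance, same order
    names: tuple[str, ...]
    r_squared: float
    f_stat: float
    f_p: float
    f_df: tuple[int, int]
    n_obs: int
    df_resid: int

    @property
    def spline_indices(self) -> np.ndarray:
        return np.asarray([self.names.index(n) for n in PREDICTOR_NAMES])

    @property
    def spline_coefficients(self) -> np.ndarray:
        return np.asarray([self.coefficients[n] for n in PREDICTOR_NAMES])

    @property
    def spline_covariance(self) -> np.ndarray:
        idx = self.spline_indices
        return self.covariance[np.ix_(idx, idx)]


def fit_model(
    records: Sequence[SpeciesTraitRecord],
    spectra: Mapping[str, Spectrum],
    basis: SplineBasis,
) -> SplineModelFit:
    """Fit log10 VOC ~ five spectral predictors + log10 SA:W by OLS.

    The observation unit is the species (one spectrum each).  The overall
    spectral effect is the 5-df F test comparing against the
    size-covariate-only model.
    """
    n = len(records)
    n_par = len(PREDICTOR_NAMES) + 2
    if n < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} species to fit, got {n}")
    rows, y = [], []
    for rec in records:
        if rec.species not in spectra:
            raise KeyError(f"no spectrum for species {rec.species!r}")
        values = proportion_spectrum(spectra[rec.species])
        preds = spectrum_predictors(values, basis)
        rows.append(np.concatenate([preds, [np.log10(rec.area_to_weight)]]))
        y.append(rec.voc_index)
    X = np.asarray(rows)
    y = np.asarray(y)
    names = ("const",) + PREDICTOR_NAMES + ("log_saw",)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient; predictors "
            f"{PREDICTOR_NAMES + ('log_saw',)} are collinear on these data"
        )
    full = sm.OLS(y, design).fit()
    reduced = sm.OLS(y, design[:, [0, -1]]).fit()
    f_stat, f_p, f_df_num = full.compare_f_test(reduced)
    return SplineModelFit(
        coefficients=dict(zip(names, (float(b) for b in full.params))),
        covariance=np.asarray(full.cov_params()),
        names=names,
        r_squared=float(full.rsquared),
        f_stat=float(f_stat),
        f_p=float(f_p),
        f_df=(int(f_df_num), int(full.df_resid)),
        n_obs=n,
        df_resid=int(full.df_resid),
    )


@dataclass(frozen=True)
class BandEffect:
    """Delta-method cumulative effect of one 100 nm colour band.

    ``cumulative_coefficient`` is the model-implied change in log10 VOC per
    unit (percent) reflectance placed uniformly in the band: the mean of
    the fitted smooth effect curve over the band's grid wavelengths.
    """

    band: str
    cumulative_coefficient: float
    std_error: float
    p_two_tailed: float
    n_wavelengths: int


def _band_contrast(basis: SplineBasis, band: str, aggregate: str) -> np.ndarray:
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    mask = band_mask(basis.grid, band)
    if not mask.any():
        raise ValueError(f"band {band!r} covers no wavelengths of the basis grid")
    rows = basis.basis_matrix[mask]
    if aggregate == "mean":
        return rows.mean(axis=0)
    if aggregate == "sum":
        return rows.sum(axis=0)
    raise ValueError("aggregate must be 'mean' or 'sum'")


def band_effect(
    fit: SplineModelFit,
    basis: SplineBasis,
    band: str,
    aggregate: str = "mean",
) -> BandEffect:
    """Back-calculate a band's cumulative coefficient and delta-method SE.

    The contrast c is the mean (or, with ``aggregate='sum'``, the summed)
    basis row over the band's grid wavelengths; the effect is c'beta with
    variance c' Sigma c, and the two-tailed p-value uses the residual-df t
    reference.
    """
    c = _band_contrast(basis, band, aggregate)
    beta = fit.spline_coefficients
    cov = fit.spline_covariance
    coef = float(c @ beta)
    var = float(c @ cov @ c)
    var = max(var, 0.0)
    se = float(np.sqrt(var))
    if se == 0.0:
        p = float("nan") if coef == 0.0 else 0.0
    else:
        p = 2.0 * float(stats.t.sf(abs(coef / se), fit.df_resid))
    n_w = int(band_mask(basis.grid, band).sum())
    return BandEffect(
        band=band,
        cumulative_coefficient=coef,
        std_error=se,
        p_two_tailed=p,
        n_wavelengths=n_w,
    )


def band_effects(
    fit: SplineModelFit, basis: SplineBasis, aggregate: str = "mean"
) -> dict[str, BandEffect]:
    """Cumulative effects for all four colour bands."""
    return {band: band_effect(fit, basis, band, aggregate) for band in BANDS}
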