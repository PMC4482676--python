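"""Derived fruit traits: ellipsoid surface area, surface-area-scaled VOC
index, brightness normalization of reflectance spectra, and colour-band
reflectance proportions.

The colour representation follows the standard four-band summary used in
fruit sensory ecology: ultraviolet (300-400 nm), blue/violet (400-500 nm),
green/yellow (500-600 nm) and orange/red (600-700 nm), each expressed as a
percentage of total reflectance in the visible range (400-700 nm).  Because
the UV numerator lies outside the visible denominator, the UV percentage is
not bounded by the other three and the three visible bands sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BANDS",
    "VISIBLE_RANGE",
    "KNUD_THOMSEN_P",
    "Spectrum",
    "ReflectanceBands",
    "FruitSample",
    "SpeciesTraitRecord",
    "ellipsoid_surface_area",
    "voc_index",
    "normalize_brightness",
    "band_proportions",
]

#: Band boundaries, half-open [low, high) except red which includes 700 nm,
#: so every wavelength in 300-700 contributes to exactly one band.
BANDS: Mapping[str, tuple[float, float]] = {
    "uv": (300.0, 400.0),
    "blue": (400.0, 500.0),
    "green": (500.0, 600.0),
    "red": (600.0, 700.0),
}

#: Visible range used as the brightness-normalization denominator.
VISIBLE_RANGE: tuple[float, float] = (400.0, 700.0)

#: Exponent of the Knud-Thomsen ellipsoid surface-area approximation
#: (maximum relative error ~1.06% over all axis ratios).
KNUD_THOMSEN_P: float = 1.6075

#: Spectrometer wavelength range; spectra outside it are rejected.
SPECTROMETER_RANGE: tuple[float, float] = (250.0, 720.0)


def band_mask(wavelengths: np.ndarray, band: str) -> np.ndarray:
    """Boolean mask of grid wavelengths belonging to *band* (see ``BANDS``)."""
    lo, hi = BANDS[band]
    w = np.asarray(wavelengths, dtype=float)
    if band == "red":
        return (w >= lo) & (w <= hi)
    return (w >= lo) & (w < hi)


def visible_mask(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    return (w >= VISIBLE_RANGE[0]) & (w <= VISIBLE_RANGE[1])


@dataclass(frozen=True)
class Spectrum:
    """Reflectance spectrum of a single fruit.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, within the spectrometer
        range 250-720 nm.
    reflectance
        Nonnegative reflectance (fraction of the white standard) at each
        wavelength.
    species
        Optional species label, used in error messages.
    normalized
        True once brightness normalization has been applied.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("wavelength grid must be a nonempty 1-D array")
        if r.shape != w.shape:
            raise ValueError(
                f"reflectance length {r.size} does not match grid length {w.size}"
            )
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        lo, hi = SPECTROMETER_RANGE
        if w[0] < lo or w[-1] > hi:
            raise ValueError(f"wavelengths must lie within [{lo}, {hi}] nm")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("reflectance values must be finite and nonnegative")

    @property
    def label(self) -> str:
        return self.species if self.species is not None else "<unnamed>"

    def visible_total(self) -> float:
        """Summed reflectance over the visible range 400-700 nm."""
        return float(self.reflectance[visible_mask(self.wavelengths)].sum())


@dataclass(frozen=True)
class ReflectanceBands:
    """Brightness-normalized band percentages plus peak hue and brightness."""

    uv: float
    blue: float
    green: float
    red: float
    lambda_max: float
    peak_brightness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "uv": self.uv,
            "blue": self.blue,
            "green": self.green,
            "red": self.red,
            "lambda_max": self.lambda_max,
            "peak_brightness": self.peak_brightness,
        }


@dataclass(frozen=True)
class FruitSample:
    """One measured fruit: caliper dimensions, weight and total VOC signal."""

    species: str
    dims: tuple[float, float, float]
    weight: float
    voc_sum: float
    spectrum: Spectrum | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"{self.species}: caliper dimensions must be positive")
        if self.weight <= 0:
            raise ValueError(f"{self.species}: weight must be positive")
        if self.voc_sum < 0:
            raise ValueError(f"{self.species}: VOC sum must be nonnegative")


@dataclass(frozen=True)
class SpeciesTraitRecord:
    """One species' trait row: the unit of the community trait table."""

    species: str
    family: str
    order: str
    voc_scaled: float  # VOC signal per unit fruit surface area
    bands: ReflectanceBands
    area_to_weight: float  # mm^2 / g
    n_fruits: int

    def __post_init__(self) -> None:
        if self.voc_scaled <= 0:
            raise ValueError(
                f"{self.species}: surface-area-scaled VOC must be positive "
                "for the log10 VOC index to be defined"
            )
        if self.area_to_weight <= 0:
            raise ValueError(f"{self.species}: area:weight ratio must be positive")

    @property
    def voc_index(self) -> float:
        """log10 of the surface-area-scaled VOC sum (the analysis scale)."""
        return float(np.log10(self.voc_scaled))


def ellipsoid_surface_area(
    dims: Sequence[float], dims_are: str = "full_axes"
) -> float:
    """Approximate ellipsoid surface area via the Knud-Thomsen formula.

    ``4*pi*[((ab)^p + (bc)^p + (ac)^p)/3]^(1/p)`` with p = 1.6075 on the
    semi-axes a, b, c.  Caliper measurements are full extents (diameters),
    so ``dims_are="full_axes"`` (the default) halves them first.

    The approximation's worst-case relative error is about 1.06%.
    """
    if len(dims) != 3:
        raise ValueError("exactly three dimensions are required")
    a, b, c = (float(d) for d in dims)
    if not all(np.isfinite(d) and d > 0 for d in (a, b, c)):
        raise ValueError(f"dimensions must be positive and finite, got {dims!r}")
    if dims_are == "full_axes":
        a, b, c = a / 2.0, b / 2.0, c / 2.0
    elif dims_are != "semi_axes":
        raise ValueError("dims_are must be 'full_axes' or 'semi_axes'")
    p = KNUD_THOMSEN_P
    return float(4.0 * np.pi * (((a * b) ** p + (b * c) ** p + (a * c) ** p) / 3.0) ** (1.0 / p))


def voc_index(
    voc_sum: float,
    area: float = 1.0,
    blank_peaks: Sequence[float] | None = None,
    species: str | None = None,
) -> float:
    """log10 surface-area-scaled VOC sum.

    ``blank_peaks`` are the integrated areas of contamination peaks found in
    blank samples of the sampling apparatus; their total is subtracted from
    the raw VOC sum before scaling.  With ``area=1`` and no blanks this is
    simply ``log10(voc_sum)`` of an already-scaled value.
    """
    label = species if species is not None else "<unnamed>"
    if area <= 0:
        raise ValueError(f"{label}: surface area must be positive")
    net = float(voc_sum) - (float(np.sum(blank_peaks)) if blank_peaks else 0.0)
    if net <= 0:
        raise ValueError(
            f"{label}: net VOC sum after blank subtraction is {net:g}; "
            "log10 VOC index undefined"
        )
    return float(np.log10(net / area))


def normalize_brightness(spectrum: Spectrum) -> Spectrum:
    """Subtract the minimum visible-range (400-700 nm) reflectance.

    Corrects for additive spectrometer drift between measurements: the
    lowest value in 400-700 nm is set to zero and the same offset is
    removed everywhere; values outside the visible range that would go
    negative are clipped at zero.  Idempotent.
    """
    vis = visible_mask(spectrum.wavelengths)
    if vis.sum() < 2:
        raise ValueError(
            f"{spectrum.label}: need at least two wavelengths in 400-700 nm "
            "to normalize brightness"
        )
    offset = float(spectrum.reflectance[vis].min())
    shifted = np.clip(spectrum.reflectance - offset, 0.0, None)
    return replace(spectrum, reflectance=shifted, normalized=True)


def band_proportions(spectrum: Spectrum) -> ReflectanceBands:
    """Summarize a brightness-normalized spectrum into band percentages.

    Each band is the summed reflectance at grid wavelengths in the band
    divided by the summed reflectance over the visible range (400-700 nm),
    as a percentage.  Peak hue (lambda_max) and peak brightness are taken
    over the visible range.
    """
    if not spectrum.normalized:
        raise ValueError(
            f"{spectrum.label}: apply normalize_brightness before computing "
            "band proportions"
        )
    w, r = spectrum.wavelengths, spectrum.reflectance
    vis = visible_mask(w)
    denom = float(r[vis].sum())
    if denom <= 0:
        raise ZeroDivisionError(
            f"{spectrum.label}: zero total visible reflectance; band "
            "proportions undefined"
        )
    pct = {
        band: 100.0 * float(r[band_mask(w, band)].sum()) / denom for band in BANDS
    }
    i_peak = int(np.flatnonzero(vis)[np.argmax(r[vis])])
    return ReflectanceBands(
        uv=pct["uv"],
        blue=pct["blue"],
        green=pct["green"],
        red=pct["red"],
        lambda_max=float(w[i_peak]),
        peak_brightness=float(r[i_peak]),
    )
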