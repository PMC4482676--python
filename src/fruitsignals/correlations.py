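"""Pearson correlation screening of the fruit trait table.

Pairwise Pearson correlations of the log10 VOC index against the four
reflectance-band percentages and the (log10) surface-area:weight ratio,
with exact two-tailed t-reference p-values.

Two transforms matter and are applied by default because they are the ones
under which the published correlation table is reproducible from the trait
table: VOC and SA:W enter on the log10 scale, and the four band
percentages are jointly renormalized by their sum (uv+blue+green+red), i.e.
converted from shares of visible (400-700 nm) reflectance to shares of
total (300-700 nm) reflectance.  Both are exposed as flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traits import SpeciesTraitRecord

__all__ = ["CorrelationResult", "CorrelationTable", "pearson_test", "correlation_matrix"]

#: Variable order of the correlation table (mirrors the published layout).
CORRELATION_VARIABLES = ("voc_index", "uv", "blue", "green", "red", "saw")

_DISPLAY = {
    "voc_index": "VOC index (log10)",
    "uv": "UV reflectance",
    "blue": "Blue reflectance",
    "green": "Green reflectance",
    "red": "Red reflectance",
    "saw": "Surface area:weight",
}


@dataclass(frozen=True)
class CorrelationResult:
    """A single Pearson correlation with its exact two-tailed t test."""

    variable_pair: tuple[str, str]
    r: float
    t_stat: float
    df: int
    p_two_tailed: float
    n: int

    @property
    def stars(self) -> str:
        if self.p_two_tailed < 0.01:
            return "**"
        if self.p_two_tailed < 0.05:
            return "*"
        return ""


def pearson_test(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Sample Pearson correlation with a two-tailed t-distribution p-value.

    t = r * sqrt(n-2) / sqrt(1-r^2) referred to Student's t with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"{labels}: inputs must be 1-D of equal length, got {x.shape} and {y.shape}"
        )
    n = x.size
    if n < 3:
        raise ValueError(f"{labels}: need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"{labels}: constant input has no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    # clamp tiny numerical overshoot before the t transform
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(
        variable_pair=labels, r=r, t_stat=float(t), df=df, p_two_tailed=p, n=n
    )


@dataclass(frozen=True)
class CorrelationTable:
    """Full pairwise correlation table over the standard trait variables."""

    r: pd.DataFrame
    p: pd.DataFrame
    results: dict[tuple[str, str], CorrelationResult]
    n: int

    def formatted(self, digits: int = 2) -> pd.DataFrame:
        """Lower-triangular string table with significance stars.

        ``*`` marks p < 0.05 and ``**`` p < 0.01, matching the published
        table's footnotes.
        """
        cols = list(self.r.columns)
        out = pd.DataFrame("", index=cols, columns=cols)
        for i, vi in enumerate(cols):
            for j, vj in enumerate(cols):
                if j < i:
                    res = self.results[(vj, vi)]
                    out.loc[vi, vj] = f"{res.r:.{digits}f}{res.stars}"
        out.index = [_DISPLAY.get(v, v) for v in cols]
        out.columns = [_DISPLAY.get(v, v) for v in cols]
        return out


def _variable_frame(
    records: Sequence[SpeciesTraitRecord],
    log_saw: bool,
    renormalize_bands: bool,
) -> pd.DataFrame:
    rows = []
    for rec in records:
        b = rec.bands
        uv, blue, green, red = b.uv, b.blue, b.green, b.red
        if renormalize_bands:
            total = uv + blue + green + red
            if total <= 0:
                raise ValueError(f"{rec.species}: zero total band reflectance")
            uv, blue, green, red = (100.0 * v / total for v in (uv, blue, green, red))
        saw = np.log10(rec.area_to_weight) if log_saw else rec.area_to_weight
        rows.append(
            {
                "species": rec.species,
                "voc_index": rec.voc_index,
                "uv": uv,
                "blue": blue,
                "green": green,
                "red": red,
                "saw": float(saw),
            }
        )
    return pd.DataFrame(rows).set_index("species")


def correlation_matrix(
    records: Sequence[SpeciesTraitRecord],
    log_saw: bool = True,
    renormalize_bands: bool = True,
) -> CorrelationTable:
    """Pairwise Pearson correlations over VOC index, bands and size.

    Parameters
    ----------
    records
        Species trait records (>= 3).
    log_saw
        Enter the surface-area:weight ratio as log10 (the regression scale).
    renormalize_bands
        Renormalize the four band percentages to sum to 100 across bands
        (shares of total 300-700 nm reflectance) before correlating.
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    frame = _variable_frame(records, log_saw=log_saw, renormalize_bands=renormalize_bands)
    cols = list(CORRELATION_VARIABLES)
    n = len(frame)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    results: dict[tuple[str, str], CorrelationResult] = {}
    for i, vi in enumerate(cols):
        for j in range(i + 1, len(cols)):
            vj = cols[j]
            try:
                res = pearson_test(frame[vi], frame[vj], labels=(vi, vj))
            except ValueError as err:
                raise ValueError(f"correlation ({vi}, {vj}) failed: {err}") from err
            results[(vi, vj)] = results[(vj, vi)] = res
            r.loc[vi, vj] = r.loc[vj, vi] = res.r
            p.loc[vi, vj] = p.loc[vj, vi] = res.p_two_tailed
    return CorrelationTable(r=r, p=p, results=results, n=n)
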