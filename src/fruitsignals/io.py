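"""Reading and writing the pipeline's file formats.

Formats are deliberately plain: a trait-table CSV (one row per species,
the column set of the packaged community table), a long-format spectra CSV
(species, wavelength_nm, reflectance) and newick trees.  The packaged
fixture ``table1_traits.csv`` carries the 56-species Madagascar dry-forest
community exactly as published (including the printed spellings and the
shared reflectance rows of two species pairs).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .traits import ReflectanceBands, SpeciesTraitRecord, Spectrum

__all__ = [
    "TRAIT_COLUMNS",
    "load_trait_table",
    "load_table1",
    "records_to_frame",
    "write_trait_table",
    "load_spectra",
    "write_spectra",
    "read_tree",
    "write_tree",
    "write_community",
]

TRAIT_COLUMNS = (
    "species",
    "family",
    "order",
    "voc",
    "uv_reflectance",
    "blue_reflectance",
    "green_reflectance",
    "red_reflectance",
    "lambda_max",
    "peak_brightness",
    "area_to_weight",
    "n_fruits",
)

_NUMERIC = TRAIT_COLUMNS[3:]


def _records_from_frame(df: pd.DataFrame, source: str) -> list[SpeciesTraitRecord]:
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{source}: duplicate species rows: {sorted(set(dupes))}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            vals = {c: float(getattr(row, c)) for c in _NUMERIC}
        except (TypeError, ValueError) as err:
            raise ValueError(f"{source}, line {i}: non-numeric field ({err})") from err
        if vals["voc"] <= 0:
            raise ValueError(
                f"{source}, line {i} ({row.species}): VOC must be positive"
            )
        if vals["area_to_weight"] <= 0:
            raise ValueError(
                f"{source}, line {i} ({row.species}): area:weight must be positive"
            )
        records.append(
            SpeciesTraitRecord(
                species=str(row.species),
                family=str(row.family),
                order=str(row.order),
                voc_scaled=vals["voc"],
                bands=ReflectanceBands(
                    uv=vals["uv_reflectance"],
                    blue=vals["blue_reflectance"],
                    green=vals["green_reflectance"],
                    red=vals["red_reflectance"],
                    lambda_max=vals["lambda_max"],
                    peak_brightness=vals["peak_brightness"],
                ),
                area_to_weight=vals["area_to_weight"],
                n_fruits=int(vals["n_fruits"]),
            )
        )
    return records


def load_trait_table(path: str | Path) -> list[SpeciesTraitRecord]:
    """Load and validate a species trait table CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return _records_from_frame(df, source=path.name)


def load_table1() -> list[SpeciesTraitRecord]:
    """The packaged 56-species community trait table."""
    with resources.files("fruitsignals.data").joinpath("table1_traits.csv").open() as fh:
        df = pd.read_csv(fh, float_precision="round_trip")
    return _records_from_frame(df, source="table1_traits.csv")


def records_to_frame(records: Sequence[SpeciesTraitRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "family": r.family,
                "order": r.order,
                "voc": r.voc_scaled,
                "uv_reflectance": r.bands.uv,
                "blue_reflectance": r.bands.blue,
                "green_reflectance": r.bands.green,
                "red_reflectance": r.bands.red,
                "lambda_max": r.bands.lambda_max,
                "peak_brightness": r.bands.peak_brightness,
                "area_to_weight": r.area_to_weight,
                "n_fruits": r.n_fruits,
            }
        )
    return pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))


def write_trait_table(records: Sequence[SpeciesTraitRecord], path: str | Path) -> None:
    # 17 significant digits: doubles survive a write/read cycle exactly
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def load_spectra(path: str | Path) -> dict[str, Spectrum]:
    """Long-format spectra CSV (species, wavelength_nm, reflectance)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"species", "wavelength_nm", "reflectance"}
    if not required.issubset(df.columns):
        raise ValueError(f"{Path(path).name}: need columns {sorted(required)}")
    out: dict[str, Spectrum] = {}
    for species, grp in df.groupby("species", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out[str(species)] = Spectrum(
            wavelengths=grp["wavelength_nm"].to_numpy(dtype=float),
            reflectance=grp["reflectance"].to_numpy(dtype=float),
            species=str(species),
        )
    return out


def write_spectra(spectra: Mapping[str, Spectrum], path: str | Path) -> None:
    rows = []
    for species, spec in spectra.items():
        for w, r in zip(spec.wavelengths, spec.reflectance):
            rows.append({"species": species, "wavelength_nm": w, "reflectance": r})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_community(community, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic community's trait table, spectra and tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": out / "traits.csv",
        "spectra": out / "spectra.csv",
        "tree": out / "tree.nwk",
    }
    write_trait_table(community.records, paths["traits"])
    write_spectra(community.spectra, paths["spectra"])
    write_tree(community.tree, paths["tree"])
    return paths
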