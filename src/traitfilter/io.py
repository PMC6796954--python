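"""Specimen-table and image input/output.

The specimen CSV schema is::

    specimen_id,taxon,species_id,life_zone,site_id,habitat,season,
    cup_color,body_volume_mm3,darkness

(UTF-8, one row per curated individual).  Tables written by the generator
carry one extra trailing column, ``cup_id``, which resolves individual
cups within an array; external tables without it are accepted, with
same-color cups within an array pooled into one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .morphometrics import DARKNESS_MAX
from .synthetic import SPECIMEN_COLUMNS

VALID_TAXA = ("bee", "fly")


@dataclass
class LoadResult:
    """A validated specimen table plus the rows rejected during loading."""

    table: pd.DataFrame
    rejected: pd.DataFrame
    summary: dict = field(default_factory=dict)


def validate_specimen_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into valid rows and rejected rows with reasons."""
    missing = [c for c in SPECIMEN_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    volume = pd.to_numeric(table["body_volume_mm3"], errors="coerce")
    darkness = pd.to_numeric(table["darkness"], errors="coerce")
    reasons = pd.Series("", index=table.index, dtype=object)
    reasons[~table["taxon"].isin(VALID_TAXA)] = (
        f"taxon not in {VALID_TAXA}")
    reasons[volume.isna() | (volume <= 0)] = "body_volume_mm3 not > 0"
    reasons[darkness.isna() | (darkness < 0) | (darkness > DARKNESS_MAX)] = (
        f"darkness out of [0,{DARKNESS_MAX}]")
    bad = reasons != ""
    valid = table[~bad].copy()
    valid["body_volume_mm3"] = volume[~bad]
    valid["darkness"] = darkness[~bad]
    rejected = table[bad].copy()
    rejected["reason"] = reasons[bad]
    rejected["row"] = np.flatnonzero(bad.to_numpy()) + 2  # 1-based + header
    return valid, rejected


def read_specimen_table(path: str | Path, on_invalid: str = "filter") -> LoadResult:
    """Read and validate a specimen CSV.

    ``on_invalid='filter'`` drops invalid rows (reported in the result);
    ``'raise'`` turns the first invalid row into a :class:`SchemaError`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"specimen_id": str, "species_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if raw.empty and raw.columns.size == 0:
        raise SchemaError(f"{path}: no header row")
    valid, rejected = validate_specimen_table(raw)
    if on_invalid == "raise" and not rejected.empty:
        first = rejected.iloc[0]
        raise SchemaError(f"{path}: row {first['row']}: {first['reason']}")
    summary = {
        "n_rows": int(len(raw)),
        "n_valid": int(len(valid)),
        "n_rejected": int(len(rejected)),
        "per_taxon": valid["taxon"].value_counts().to_dict(),
        "per_zone": valid["life_zone"].value_counts().to_dict(),
    }
    return LoadResult(valid.reset_index(drop=True), rejected, summary)


def write_specimen_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a specimen CSV in canonical column order (cup_id last)."""
    cols = list(SPECIMEN_COLUMNS)
    if "cup_id" in table.columns:
        cols.append("cup_id")
    table[cols].to_csv(path, index=False)


# ----------------------------------------------------------------------
# image I/O (PNG/TIFF grayscale; mask as a companion single-channel image)

def save_image_set(images, directory: str | Path, stem: str) -> None:
    """Write a three-view image set as PNGs with companion mask files."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for view in ("dorsal", "lateral", "anterior"):
        vi = getattr(images, view)
        iio.imwrite(directory / f"{stem}_{view}.png", vi.image)
        iio.imwrite(directory / f"{stem}_{view}_mask.png",
                    (vi.mask.astype(np.uint8) * 255))


def load_image_set(directory: str | Path, stem: str, pixel_scale: float):
    """Read a three-view image set written by :func:`save_image_set`."""
    import imageio.v3 as iio

    from .morphometrics import SpecimenImageSet, ViewImage

    directory = Path(directory)
    views = {}
    for view in ("dorsal", "lateral", "anterior"):
        image = iio.imread(directory / f"{stem}_{view}.png")
        mask = iio.imread(directory / f"{stem}_{view}_mask.png") > 0
        views[view] = ViewImage(image=image, mask=mask)
    return SpecimenImageSet(pixel_scale=pixel_scale, **views)
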