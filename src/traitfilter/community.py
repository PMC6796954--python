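"""Cup-level community samples, community-weighted means and trait ranges.

The sampling unit is the pollinator cup: all individuals of one taxon
caught in one cup during one season form a :class:`CupSample`.  The
community-weighted mean (CWM) of a trait is by default the plain mean over
individuals (each captured individual carries weight one, which realizes
abundance weighting); a species-mean mode averages species means weighted
by their abundance in the cup.  The trait range (max - min over
individuals) feeds the null model; samples with fewer than two individuals
have an undefined range and are excluded from SES analysis but retained
for CWM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, SchemaError

TRAIT_COLUMNS = {"volume": "body_volume_mm3", "darkness": "darkness"}

_DESIGN_LABELS = ("life_zone", "site_id", "habitat", "season")


def trait_column(trait: str) -> str:
    try:
        return TRAIT_COLUMNS[trait]
    except KeyError:
        raise InputError(
            f"unknown trait {trait!r}; expected one of {tuple(TRAIT_COLUMNS)}"
        ) from None


@dataclass
class CupSample:
    """All individuals of one taxon from one cup in one season."""

    sample_id: str
    taxon: str
    life_zone: str
    site_id: str
    habitat: str
    season: str
    members: pd.DataFrame = field(repr=False)

    @property
    def n_individuals(self) -> int:
        return len(self.members)

    def trait_values(self, trait: str) -> np.ndarray:
        return self.members[trait_column(trait)].to_numpy(dtype=float)


@dataclass
class CWMResult:
    sample_id: str
    trait: str
    cwm: float
    n_individuals: int


def group_samples(table: pd.DataFrame) -> list[CupSample]:
    """Partition a specimen table into per-(cup, season, taxon) samples.

    Uses the ``cup_id`` column when present; otherwise the cup is resolved
    as (life_zone, site_id, habitat, season, cup_color), which pools
    same-color cups within an array.  Every row lands in exactly one
    sample; empty cups are simply absent.
    """
    required = {"taxon", "body_volume_mm3", "darkness", *_DESIGN_LABELS}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"specimen table lacks columns: {sorted(missing)}")
    if "cup_id" in table.columns:
        cup_key = table["cup_id"].astype(str)
    else:
        cup_key = (
            table["life_zone"].astype(str) + "." + table["site_id"].astype(str)
            + "." + table["habitat"].astype(str) + "." + table["season"].astype(str)
            + "." + table["cup_color"].astype(str)
        )
    samples = []
    for (cup, season, taxon), members in table.groupby(
        [cup_key, table["season"], table["taxon"]], sort=True
    ):
        first = members.iloc[0]
        samples.append(CupSample(
            sample_id=f"{cup}|{taxon}",
            taxon=str(taxon),
            life_zone=str(first["life_zone"]),
            site_id=str(first["site_id"]),
            habitat=str(first["habitat"]),
            season=str(season),
            members=members,
        ))
    return samples


def cwm(sample: CupSample, trait: str, mode: str = "individual") -> CWMResult:
    """Community-weighted mean of a trait for one cup sample.

    ``individual`` mode (default) averages the individual trait values;
    ``species_mean`` averages per-species mean traits weighted by the
    number of individuals per species, which collapses to the same value
    when individuals carry their species mean.
    """
    if sample.n_individuals < 1:
        raise InputError(f"sample {sample.sample_id} is empty")
    col = trait_column(trait)
    if mode == "individual":
        value = float(sample.members[col].mean())
    elif mode == "species_mean":
        per_species = sample.members.groupby("species_id")[col].agg(["mean", "size"])
        value = float(np.average(per_species["mean"], weights=per_species["size"]))
    else:
        raise InputError(f"unknown CWM mode {mode!r}")
    return CWMResult(sample.sample_id, trait, value, sample.n_individuals)


def trait_range(sample: CupSample, trait: str) -> float:
    """max - min of the trait over individuals; undefined below n = 2."""
    if sample.n_individuals < 2:
        raise InputError(
            f"sample {sample.sample_id} has n={sample.n_individuals}; the "
            "trait range is undefined below 2 individuals"
        )
    values = sample.trait_values(trait)
    return float(values.max() - values.min())


def trait_correlation(table: pd.DataFrame, taxon: str) -> tuple[float, float]:
    """Pearson correlation between individual volume and darkness.

    Used to justify analyzing the two traits independently; returns
    ``(r, two-sided p)``.
    """
    sub = table[table["taxon"] == taxon]
    if len(sub) < 3:
        raise InputError(f"need >= 3 individuals of taxon {taxon!r}, got {len(sub)}")
    x = sub["body_volume_mm3"].to_numpy(dtype=float)
    y = sub["darkness"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined: a trait has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cwm_table(samples: list[CupSample], traits=("volume", "darkness"),
              mode: str = "individual") -> pd.DataFrame:
    """Long-format CWM table over samples and traits."""
    rows = []
    for s in samples:
        for trait in traits:
            res = cwm(s, trait, mode=mode)
            rows.append((s.sample_id, s.taxon, s.life_zone, s.site_id,
                         s.habitat, s.season, trait, res.cwm, res.n_individuals))
    return pd.DataFrame(rows, columns=[
        "sample_id", "taxon", "life_zone", "site_id", "habitat", "season",
        "trait", "cwm", "n_individuals",
    ])


def range_table(samples: list[CupSample], traits=("volume", "darkness")) -> pd.DataFrame:
    """Long-format trait-range table; samples with n < 2 are omitted."""
    rows = []
    for s in samples:
        if s.n_individuals < 2:
            continue
        for trait in traits:
            rows.append((s.sample_id, s.taxon, s.life_zone, s.site_id,
                         s.habitat, s.season, trait, trait_range(s, trait),
                         s.n_individuals))
    return pd.DataFrame(rows, columns=[
        "sample_id", "taxon", "life_zone", "site_id", "habitat", "season",
        "trait", "trait_range", "n_individuals",
    ])
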