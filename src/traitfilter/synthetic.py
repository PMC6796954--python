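"""Synthetic specimen-survey generator.

Produces specimen tables with the statistical structure the downstream
analysis assumes: a species pool per taxon whose richness declines with
elevation, per-zone trait targets (community means of ellipsoid body volume
and 0-222 body darkness), a log-normal rank-abundance structure, and a
tunable per-zone *filtering strength*.

Filtering is what distinguishes the two taxa in the emulated system.  For
bees it is implemented as quantile truncation of the species pool at high
elevation — species trait means are drawn from a central quantile window
of the zone distribution (truncation symmetric about the median, window
width shrinking with filtering strength) and recentred on the configured
zone mean, so the trait *range* narrows while the community mean stays on
target.  For flies the same control shifts the mean only (no range
narrowing).

Species keep their trait rank across zones (comonotonic quantile draws), so
species occupying several zones show within-species trait trends along the
gradient, mirroring intraspecific variation in real surveys.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig, TAXA, TRAITS
from .errors import ConfigError, InputError
from .morphometrics import DARKNESS_MAX

#: canonical specimen-table column order (cup_id is appended as an
#: artifact-specific resolver for individual cups; see io module notes)
SPECIMEN_COLUMNS = [
    "specimen_id", "taxon", "species_id", "life_zone", "site_id",
    "habitat", "season", "cup_color", "body_volume_mm3", "darkness",
]


# ----------------------------------------------------------------------
# design

def build_design(config: GeneratorConfig) -> pd.DataFrame:
    """One row per physical cup per season (an empty cup-sample slot).

    With the default configuration (``site_array`` layout: one 12-cup array
    per site, habitat an array-level label) this yields 108 slots per
    season, 216 in total.  The ``habitat_arrays`` layout deploys one array
    per site and habitat instead.
    """
    config.validate()
    per_color = config.n_cups_per_array // len(config.cup_colors)
    rows = []
    for zi, zone in enumerate(config.life_zones):
        for si in range(config.n_sites_per_zone):
            site_id = f"{zone.label}_site{si + 1}"
            if config.layout == "site_array":
                # habitat assigned at the array level, cycling within zone
                arrays = [config.habitats[si % len(config.habitats)]]
            else:
                arrays = list(config.habitats)
            for habitat in arrays:
                for season in config.seasons:
                    for ci in range(config.n_cups_per_array):
                        color = config.cup_colors[ci // per_color]
                        cup_id = f"{site_id}.{habitat}.{season}.cup{ci + 1:02d}"
                        rows.append((
                            zone.label, zi, site_id, habitat, season,
                            color, cup_id,
                        ))
    return pd.DataFrame(
        rows,
        columns=["life_zone", "zone_index", "site_id", "habitat", "season",
                 "cup_color", "cup_id"],
    )


# ----------------------------------------------------------------------
# trait distributions

def _zone_trait_dist(trait: str, family: str, mean: float, sd: float):
    """Frozen scipy distribution for a zone-level trait target."""
    if trait == "volume":
        if family == "lognormal":
            sigma2 = math.log(1.0 + (sd / mean) ** 2)
            return stats.lognorm(s=math.sqrt(sigma2),
                                 scale=math.exp(math.log(mean) - sigma2 / 2))
        if family == "gamma":
            return stats.gamma(a=(mean / sd) ** 2, scale=sd ** 2 / mean)
        raise ConfigError(f"unknown volume_family {family!r}")
    if trait == "darkness":
        if family == "beta":
            mu, sig = mean / DARKNESS_MAX, sd / DARKNESS_MAX
            if sig ** 2 >= mu * (1.0 - mu):
                raise ConfigError(
                    f"darkness sd {sd} too large for mean {mean} under the "
                    "beta family"
                )
            nu = mu * (1.0 - mu) / sig ** 2 - 1.0
            return stats.beta(a=mu * nu, b=(1.0 - mu) * nu, scale=DARKNESS_MAX)
        if family == "normal":
            return stats.norm(loc=mean, scale=sd)
        raise ConfigError(f"unknown darkness_family {family!r}")
    raise InputError(f"unknown trait {trait!r}")


def truncation_window(strength: float) -> float:
    """Map a filtering strength >= 0 onto a retained quantile width in (0, 1].

    ``w = exp(-strength)``: zero strength retains the full distribution;
    increasing strength truncates the species pool symmetrically about its
    median to a central quantile window of width ``w``, so the trait SD of
    the filtered pool shrinks monotonically and tends to zero.
    """
    if strength < 0:
        raise InputError(f"filtering strength must be >= 0, got {strength}")
    return math.exp(-strength)


def _truncated_offset(dist, w: float, target_mean: float, n_grid: int = 4001) -> float:
    """Recentring offset so the window-truncated draw keeps the target mean."""
    mid = (np.arange(n_grid) + 0.5) / n_grid
    lo = 0.5 - w / 2.0
    return float(np.mean(dist.ppf(lo + w * mid))) - target_mean


def _clip_trait(trait: str, values: np.ndarray) -> np.ndarray:
    if trait == "darkness":
        return np.clip(values, 0.0, float(DARKNESS_MAX))
    return np.maximum(values, 1e-9)


# ----------------------------------------------------------------------
# species pool

def draw_species_pool(config: GeneratorConfig, taxon: str,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Regional species pool for one taxon, in long (species x zone) form.

    Returns one row per species per occupied zone with columns
    ``taxon, species_id, life_zone, zone_index, base_weight,
    relative_abundance, volume_mean, darkness_mean``.
    ``relative_abundance`` sums to 1 within each zone.
    """
    if taxon not in TAXA:
        raise InputError(f"unknown taxon {taxon!r}; expected one of {TAXA}")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sp = config.n_species(taxon)
    nz = config.n_life_zones
    ids = np.array([f"{taxon}_sp{i + 1:03d}" for i in range(n_sp)])

    # comonotonic species quantiles: a species keeps its trait rank across
    # zones, producing intraspecific trends when zone targets shift
    u = {trait: rng.uniform(size=n_sp) for trait in TRAITS}
    base_weight = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_sp)

    occ_p = np.asarray(config.zone_occupancy[taxon], dtype=float)
    occupancy = rng.uniform(size=(n_sp, nz)) < occ_p[None, :]
    none = ~occupancy.any(axis=1)
    if none.any():
        fallback = rng.choice(nz, size=int(none.sum()), p=occ_p / occ_p.sum())
        occupancy[np.flatnonzero(none), fallback] = True

    mode = config.filtering_mode[taxon]
    families = {"volume": config.volume_family, "darkness": config.darkness_family}
    records = []
    for zi, zone in enumerate(config.life_zones):
        members = np.flatnonzero(occupancy[:, zi])
        if members.size == 0:
            continue
        strength = config.filtering_strength[taxon][zi]
        means = {}
        for trait in TRAITS:
            target = config.zone_trait_means[taxon][trait][zi]
            sd = config.zone_trait_sds[taxon][trait][zi]
            dist = _zone_trait_dist(trait, families[trait], target, sd)
            uu = u[trait][members]
            if strength > 0 and mode == "truncate":
                w = truncation_window(strength)
                vals = dist.ppf(0.5 - w / 2.0 + w * uu)
                vals = vals - _truncated_offset(dist, w, target)
            elif strength > 0 and mode == "shift":
                vals = dist.ppf(uu) + strength * sd
            else:
                vals = dist.ppf(uu)
            means[trait] = _clip_trait(trait, np.asarray(vals, dtype=float))
        w = base_weight[members]
        rel = w / w.sum()
        records.append(pd.DataFrame({
            "taxon": taxon,
            "species_id": ids[members],
            "life_zone": zone.label,
            "zone_index": zi,
            "base_weight": w,
            "relative_abundance": rel,
            "volume_mean": means["volume"],
            "darkness_mean": means["darkness"],
        }))
    return pd.concat(records, ignore_index=True)


# ----------------------------------------------------------------------
# dataset assembly

def assemble_dataset(config: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full synthetic specimen table (one row per captured individual).

    Individuals are allocated to zones by the per-taxon abundance weights,
    to cup slots uniformly within zone, and to species by within-zone
    relative abundance.  Individual traits are the species-by-zone mean
    plus individual noise (multiplicative log-normal for volume, additive
    normal clipped to [0, 222] for darkness), both mean-preserving.
    Row counts equal the configured per-taxon totals exactly and identical
    (config, seed) pairs reproduce the table bit for bit.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = build_design(config)
    cv = config.individual_noise_cv
    sig_mult = math.sqrt(math.log(1.0 + cv ** 2)) if cv > 0 else 0.0

    frames = []
    for taxon in TAXA:
        n = config.n_individuals(taxon)
        if n == 0:
            continue
        pool = draw_species_pool(config, taxon, rng)
        zone_w = np.asarray(config.zone_abundance[taxon], dtype=float)
        present = np.isin(np.arange(config.n_life_zones),
                          pool["zone_index"].unique())
        zone_w = np.where(present, zone_w, 0.0)
        if zone_w.sum() <= 0:
            raise ConfigError(f"no occupied zone has positive abundance for {taxon}")
        zone_w = zone_w / zone_w.sum()
        zone_of = rng.choice(config.n_life_zones, size=n, p=zone_w)

        cols = {c: np.empty(n, dtype=object)
                for c in ("species_id", "life_zone", "site_id", "habitat",
                          "season", "cup_color", "cup_id")}
        volume = np.empty(n)
        darkness = np.empty(n)
        for zi in np.unique(zone_of):
            idx = np.flatnonzero(zone_of == zi)
            zpool = pool[pool["zone_index"] == zi].reset_index(drop=True)
            zslots = design[design["zone_index"] == zi].reset_index(drop=True)
            shape = config.catch_clumping_shape
            if shape is None:
                slot_pick = rng.integers(len(zslots), size=idx.size)
            else:
                # overdispersed catches: cup attractiveness ~ Gamma(shape)
                w = rng.gamma(shape, 1.0, size=len(zslots))
                slot_pick = rng.choice(len(zslots), size=idx.size, p=w / w.sum())
            sp_pick = rng.choice(len(zpool), size=idx.size,
                                 p=zpool["relative_abundance"].to_numpy())
            for col in ("life_zone", "site_id", "habitat", "season",
                        "cup_color", "cup_id"):
                cols[col][idx] = zslots[col].to_numpy()[slot_pick]
            cols["species_id"][idx] = zpool["species_id"].to_numpy()[sp_pick]
            vmean = zpool["volume_mean"].to_numpy()[sp_pick]
            dmean = zpool["darkness_mean"].to_numpy()[sp_pick]
            if cv > 0:
                volume[idx] = vmean * rng.lognormal(
                    mean=-0.5 * sig_mult ** 2, sigma=sig_mult, size=idx.size)
                darkness[idx] = np.clip(
                    rng.normal(dmean, cv * np.maximum(dmean, 1e-9)),
                    0.0, float(DARKNESS_MAX))
            else:
                volume[idx] = vmean
                darkness[idx] = dmean
        frames.append(pd.DataFrame({
            "specimen_id": [f"{taxon}{i + 1:05d}" for i in range(n)],
            "taxon": taxon,
            "species_id": cols["species_id"],
            "life_zone": cols["life_zone"],
            "site_id": cols["site_id"],
            "habitat": cols["habitat"],
            "season": cols["season"],
            "cup_color": cols["cup_color"],
            "body_volume_mm3": np.maximum(volume, 1e-9),
            "darkness": darkness,
            "cup_id": cols["cup_id"],
        }))
    if not frames:
        raise ConfigError("at least one taxon must have individuals to assemble")
    return pd.concat(frames, ignore_index=True)
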