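"""Study-design and generator configuration.

The default :class:`GeneratorConfig` encodes the pan-trap study design the
package emulates: three forested life zones on an elevation gradient
(ponderosa pine ~2,400 m, mixed conifer ~2,600 m, spruce-fir ~3,200 m),
three sites per zone, a 12-cup elevated pan-trap array per site (4 white,
4 yellow, 4 blue cups), sampled in a pre-monsoon and a monsoon season, and
a regional pool of 178 bee and 96 fly species contributing 1,283 and 639
curated specimens respectively.

Per-zone trait targets (ellipsoid body volume in mm^3, body darkness on the
0-222 inverted-intensity scale) and a per-zone "filtering strength" control
the trait structure: bee species pools at high elevation are truncated to a
central quantile window of the trait distribution (range narrowing, with
recentring so the community mean stays on target), flies are shifted in
mean only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigError
from .morphometrics import DARKNESS_MAX

TAXA = ("bee", "fly")
TRAITS = ("volume", "darkness")

#: layout of pan-trap arrays: one array per site (habitat is an array-level
#: label; 108 cups/season with the default counts) or one array per
#: site x habitat (216 cups/season).
LAYOUTS = ("site_array", "habitat_arrays")

FILTERING_MODES = ("truncate", "shift")


@dataclass(frozen=True)
class LifeZone:
    """An elevation-defined vegetation band."""

    label: str
    elevation_m: float
    mean_annual_temp_c: float


DEFAULT_LIFE_ZONES = (
    LifeZone("ponderosa", 2400.0, 9.6),
    LifeZone("mixed_conifer", 2600.0, 7.4),
    LifeZone("spruce_fir", 3200.0, 5.2),
)


def _per_zone(mapping: Mapping[str, Sequence[float]]) -> dict:
    return {k: tuple(float(x) for x in v) for k, v in mapping.items()}


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic trait-survey dataset.

    Trait targets default to the zone-level community means the analysis is
    meant to recover (bee darkness 35/35/78; bee volume 302/302/598 mm^3;
    fly darkness 14.90/31.21/34.69; fly volume 100/145/286 mm^3).
    """

    life_zones: tuple[LifeZone, ...] = DEFAULT_LIFE_ZONES
    n_sites_per_zone: int = 3
    habitats: tuple[str, ...] = ("forest", "meadow")
    n_cups_per_array: int = 12
    cup_colors: tuple[str, ...] = ("white", "yellow", "blue")
    seasons: tuple[str, ...] = ("pre_monsoon", "monsoon")
    layout: str = "site_array"

    n_bee_species: int = 178
    n_fly_species: int = 96
    n_bee_individuals: int = 1283
    n_fly_individuals: int = 639

    # per-taxon {trait: (value per zone, low to high elevation)}
    zone_trait_means: dict = field(default_factory=lambda: {
        "bee": {"volume": (302.0, 302.0, 598.0), "darkness": (35.0, 35.0, 78.0)},
        "fly": {"volume": (100.0, 145.0, 286.0), "darkness": (14.90, 31.21, 34.69)},
    })
    zone_trait_sds: dict = field(default_factory=lambda: {
        "bee": {"volume": (250.0, 250.0, 450.0), "darkness": (18.0, 18.0, 18.0)},
        "fly": {"volume": (80.0, 110.0, 200.0), "darkness": (8.0, 12.0, 12.0)},
    })

    # per-taxon per-zone scalar >= 0; 0 means no trait-based filtering
    filtering_strength: dict = field(default_factory=lambda: {
        "bee": (0.0, 0.0, 3.0),
        "fly": (0.0, 0.0, 0.0),
    })
    # bees: quantile truncation of the species pool; flies: mean shift only
    filtering_mode: dict = field(default_factory=lambda: {
        "bee": "truncate",
        "fly": "shift",
    })

    # probability that a species occupies each zone (richness declines with
    # elevation) and per-zone share of captured individuals (bees decline,
    # flies increase with elevation)
    zone_occupancy: dict = field(default_factory=lambda: {
        "bee": (0.70, 0.50, 0.25),
        "fly": (0.60, 0.55, 0.50),
    })
    zone_abundance: dict = field(default_factory=lambda: {
        "bee": (0.40, 0.33, 0.27),
        "fly": (0.20, 0.30, 0.50),
    })

    #: log-sd of the species abundance weights (log-normal rank-abundance)
    abundance_sigma: float = 1.0
    #: gamma shape of per-cup attractiveness weights; pan-trap catches are
    #: overdispersed, so expected catch varies between cups (1.0 gives
    #: exponential weights; None gives equal expected catch per cup)
    catch_clumping_shape: float | None = 1.0
    #: individual-level trait noise, as a coefficient of variation of the
    #: species-by-zone mean
    individual_noise_cv: float = 0.07

    volume_family: str = "lognormal"
    darkness_family: str = "beta"

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def n_life_zones(self) -> int:
        return len(self.life_zones)

    @property
    def zone_labels(self) -> tuple[str, ...]:
        return tuple(z.label for z in self.life_zones)

    def n_species(self, taxon: str) -> int:
        return {"bee": self.n_bee_species, "fly": self.n_fly_species}[taxon]

    def n_individuals(self, taxon: str) -> int:
        return {"bee": self.n_bee_individuals, "fly": self.n_fly_individuals}[taxon]

    # ------------------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        """Raise :class:`ConfigError` naming the first offending field."""
        counts = {
            "n_sites_per_zone": self.n_sites_per_zone,
            "n_cups_per_array": self.n_cups_per_array,
            "n_bee_species": self.n_bee_species,
            "n_fly_species": self.n_fly_species,
        }
        for name, value in counts.items():
            if not isinstance(value, (int,)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        # a taxon may be absent entirely (0 individuals) but not negative
        for name in ("n_bee_individuals", "n_fly_individuals"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or value < 0:
                raise ConfigError(f"{name} must be an integer >= 0, got {value!r}")
        if len(self.life_zones) < 1:
            raise ConfigError("life_zones must contain at least one zone")
        if len(set(self.zone_labels)) != len(self.zone_labels):
            raise ConfigError("life_zones labels must be unique")
        if self.layout not in LAYOUTS:
            raise ConfigError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")
        if not self.habitats or not self.seasons or not self.cup_colors:
            raise ConfigError("habitats, seasons and cup_colors must be nonempty")
        if self.n_cups_per_array % len(self.cup_colors) != 0:
            raise ConfigError(
                "n_cups_per_array must be divisible by the number of cup_colors"
            )
        nz = self.n_life_zones
        for taxon in TAXA:
            for trait in TRAITS:
                means = self.zone_trait_means[taxon][trait]
                sds = self.zone_trait_sds[taxon][trait]
                if len(means) != nz or len(sds) != nz:
                    raise ConfigError(
                        f"zone_trait_means/sds[{taxon}][{trait}] must have "
                        f"{nz} per-zone entries"
                    )
                if any(s <= 0 for s in sds):
                    raise ConfigError(f"zone_trait_sds[{taxon}][{trait}] must be > 0")
                if trait == "volume" and any(m <= 0 for m in means):
                    raise ConfigError(
                        f"zone_trait_means[{taxon}][volume] must be > 0"
                    )
                if trait == "darkness" and any(
                    not (0.0 <= m <= DARKNESS_MAX) for m in means
                ):
                    raise ConfigError(
                        f"zone_trait_means[{taxon}][darkness] must lie in "
                        f"[0, {DARKNESS_MAX}]"
                    )
            for name in ("filtering_strength", "zone_occupancy", "zone_abundance"):
                vec = getattr(self, name)[taxon]
                if len(vec) != nz:
                    raise ConfigError(f"{name}[{taxon}] must have {nz} entries")
            if any(s < 0 for s in self.filtering_strength[taxon]):
                raise ConfigError(f"filtering_strength[{taxon}] must be >= 0")
            if any(not (0.0 < p <= 1.0) for p in self.zone_occupancy[taxon]):
                raise ConfigError(f"zone_occupancy[{taxon}] must lie in (0, 1]")
            if any(w < 0 for w in self.zone_abundance[taxon]) or sum(
                self.zone_abundance[taxon]
            ) <= 0:
                raise ConfigError(f"zone_abundance[{taxon}] must be nonnegative "
                                  "with positive sum")
            if self.filtering_mode[taxon] not in FILTERING_MODES:
                raise ConfigError(
                    f"filtering_mode[{taxon}] must be one of {FILTERING_MODES}"
                )
        if self.abundance_sigma < 0:
            raise ConfigError("abundance_sigma must be >= 0")
        if self.catch_clumping_shape is not None and self.catch_clumping_shape <= 0:
            raise ConfigError("catch_clumping_shape must be > 0 or None")
        if self.individual_noise_cv < 0:
            raise ConfigError("individual_noise_cv must be >= 0")
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["life_zones"] = [asdict(z) for z in self.life_zones]
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        data = dict(data)
        if "life_zones" in data:
            data["life_zones"] = tuple(
                LifeZone(**z) if isinstance(z, Mapping) else z
                for z in data["life_zones"]
            )
        for key in ("habitats", "cup_colors", "seasons"):
            if key in data:
                data[key] = tuple(data[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        # normalize per-zone sequences to tuples
        for attr in ("zone_trait_means", "zone_trait_sds"):
            val = getattr(cfg, attr)
            setattr(cfg, attr, {t: _per_zone(v) for t, v in val.items()})
        for attr in ("filtering_strength", "zone_occupancy", "zone_abundance"):
            setattr(cfg, attr, _per_zone(getattr(cfg, attr)))
        return cfg.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML superset also parses JSON
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable sha256 digest of the configuration (reproducibility tag)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()
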