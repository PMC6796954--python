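"""End-to-end orchestration: generate -> group -> CWM/range -> SES -> ANOVA.

A single run seed fans out deterministically to per-stage child seeds
(dataset generation and null-model draws), so each stage is independently
reproducible and a full run is bit-identical under a fixed (config, seed)
pair.  Results are returned as a :class:`ResultBundle` of data frames and,
when an output directory is given, persisted as CSVs plus a JSON run-
metadata file carrying the config hash, seed, null-model settings and
package version.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import cwm_table, group_samples, range_table, trait_correlation
from .config import GeneratorConfig, TAXA, TRAITS
from .errors import InputError
from .inference import intraspecific_trends, zone_summary
from .io import write_specimen_table
from .nullmodel import (DEFAULT_B, DEFAULT_THRESHOLD, RegionalPool, ses_table)
from .synthetic import assemble_dataset


@dataclass
class ResultBundle:
    """All tables produced by one pipeline run, plus run metadata."""

    specimen_table: pd.DataFrame
    cwm_table: pd.DataFrame
    range_table: pd.DataFrame
    ses_table: pd.DataFrame
    anova_table: pd.DataFrame
    tukey_table: pd.DataFrame
    zone_stats: pd.DataFrame
    intraspecific_table: pd.DataFrame
    correlations: pd.DataFrame
    run_metadata: dict = field(default_factory=dict)

    _CSV = (
        ("specimen_table", "specimens.csv"),
        ("cwm_table", "cwm.csv"),
        ("range_table", "ranges.csv"),
        ("ses_table", "ses.csv"),
        ("anova_table", "anova.csv"),
        ("tukey_table", "tukey.csv"),
        ("zone_stats", "zone_stats.csv"),
        ("intraspecific_table", "intraspecific.csv"),
        ("correlations", "trait_correlations.csv"),
    )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for attr, name in self._CSV:
            table = getattr(self, attr)
            if attr == "specimen_table":
                write_specimen_table(table, out_dir / name)
            else:
                table.to_csv(out_dir / name, index=False)
        with open(out_dir / "run_metadata.json", "w", encoding="utf-8") as fh:
            json.dump(self.run_metadata, fh, indent=2, sort_keys=True)


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Deterministic per-stage RNG streams derived from one run seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(2)
    return {
        "generate": np.random.default_rng(children[0]),
        "null_model": np.random.default_rng(children[1]),
    }


def analyze_specimen_table(table: pd.DataFrame, seed: int = 0,
                           B: int = DEFAULT_B, mode: str = "sd",
                           threshold: float = DEFAULT_THRESHOLD,
                           taxa=TAXA, traits=TRAITS,
                           unit: str = "cup",
                           min_zones: int = 3,
                           zone_order=None) -> dict:
    """Run the full analysis on an existing specimen table.

    Returns a dict with sample lists and all result tables; used both by
    :func:`run_pipeline` and when ingesting external data.
    """
    rng = stage_rngs(seed)["null_model"]
    table = table[table["taxon"].isin(taxa)]
    if table.empty:
        raise InputError("specimen table holds no rows for the requested taxa")
    if zone_order is None:
        zone_order = list(pd.unique(table["life_zone"]))
    samples = group_samples(table)
    cwm = cwm_table(samples, traits=traits)
    ranges = range_table(samples, traits=traits)
    ses_frames = []
    for taxon in taxa:
        taxon_samples = [s for s in samples if s.taxon == taxon]
        if not taxon_samples:
            continue
        for trait in traits:
            pool = RegionalPool.from_table(table, taxon, trait)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ses_frames.append(ses_table(
                    taxon_samples, pool, trait, B=B, mode=mode,
                    threshold=threshold, rng=rng))
    ses = (pd.concat(ses_frames, ignore_index=True) if ses_frames
           else pd.DataFrame())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = zone_summary(cwm, ses, zone_order=zone_order, unit=unit)
        intra = intraspecific_trends(table, min_zones=min_zones,
                                     zone_order=zone_order)
    corr_rows = []
    for taxon in taxa:
        try:
            r, p = trait_correlation(table, taxon)
            corr_rows.append((taxon, r, p))
        except InputError:
            continue
    return {
        "samples": samples, "cwm": cwm, "ranges": ranges, "ses": ses,
        "summary": summary, "intraspecific": intra,
        "correlations": pd.DataFrame(corr_rows, columns=["taxon", "r", "p"]),
        "zone_order": zone_order,
    }


def run_pipeline(config: GeneratorConfig | str | Path | None = None,
                 seed: int = 0, out_dir: str | Path | None = None,
                 B: int = DEFAULT_B, mode: str = "sd",
                 threshold: float = DEFAULT_THRESHOLD,
                 taxa=TAXA, traits=TRAITS, unit: str = "cup") -> ResultBundle:
    """Full synthetic run: generate a dataset, then analyze it.

    ``config`` may be a :class:`GeneratorConfig`, a YAML/JSON path, or
    ``None`` for the default study design.  ``seed`` controls all
    randomness.  When ``out_dir`` is given the bundle is persisted there.
    """
    if config is None:
        config = GeneratorConfig()
    elif not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_file(config)
    config.validate()
    rngs = stage_rngs(seed)
    table = assemble_dataset(config, rngs["generate"])
    results = analyze_specimen_table(
        table, seed=seed, B=B, mode=mode, threshold=threshold,
        taxa=taxa, traits=traits, unit=unit,
        zone_order=list(config.zone_labels))
    bundle = ResultBundle(
        specimen_table=table,
        cwm_table=results["cwm"],
        range_table=results["ranges"],
        ses_table=results["ses"],
        anova_table=results["summary"]["anova"],
        tukey_table=results["summary"]["tukey"],
        zone_stats=results["summary"]["zone_stats"],
        intraspecific_table=results["intraspecific"],
        correlations=results["correlations"],
        run_metadata={
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": int(seed),
            "B": int(B),
            "mode": mode,
            "threshold": float(threshold),
            "taxa": list(taxa),
            "traits": list(traits),
            "unit": unit,
            "n_specimens": int(len(table)),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        },
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
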