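"""Zone-level statistical summaries and intraspecific trend analysis.

One-way fixed-effects ANOVA with life zone as the only predictor is run on
cup-level community metrics (CWM and sesRange of volume and darkness, per
taxon — eight analyses in the default design), followed by Tukey HSD
multiple comparisons.  Cups are pooled across sites, habitats and seasons
by default; a site-mean aggregation mode is available for designs where
the site is the preferred replication unit.

Intraspecific trends test, for each species present in at least
``min_zones`` life zones, whether its trait mean changes across zones
(one-way ANOVA) and sign the trend (+/-) by the slope of zone means
against elevation rank when significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import TRAIT_COLUMNS, trait_column
from .errors import InputError


@dataclass
class AnovaResult:
    response: str
    groups: list[str]
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)
    tukey: list = field(default_factory=list)  # (group_a, group_b, p_adj)


@dataclass
class IntraspecificTrend:
    species_id: str
    taxon: str
    trait: str
    zone_means: dict
    df: int
    F: float
    p: float
    direction: str  # '+', '-' or 'none'


# ----------------------------------------------------------------------

def _group_values(values, order=None):
    groups: dict[str, list[float]] = {}
    for label, value in values:
        groups.setdefault(str(label), []).append(float(value))
    if order is not None:
        ordered = [g for g in order if g in groups]
        ordered += [g for g in groups if g not in ordered]
    else:
        ordered = list(groups)
    return {g: np.asarray(groups[g]) for g in ordered}


def anova_oneway(values, order=None, response: str = "") -> AnovaResult:
    """Classical fixed-effects one-way ANOVA over (group, value) pairs.

    Requires at least two groups with two values each and nonzero
    within-group variance somewhere; group means/SDs and Tukey HSD
    adjusted p-values for every group pair are attached.
    """
    groups = _group_values(values, order)
    if len(groups) < 2:
        raise InputError(f"need >= 2 groups, got {len(groups)}")
    for g, v in groups.items():
        if v.size < 2:
            raise InputError(f"group {g!r} has fewer than 2 values")
    arrays = list(groups.values())
    if all(np.ptp(v) == 0 for v in arrays):
        raise InputError("degenerate data: zero variance within every group")
    F, p = stats.f_oneway(*arrays)
    df_between = len(groups) - 1
    df_within = sum(v.size for v in arrays) - len(groups)
    labels = list(groups)
    res = AnovaResult(
        response=response, groups=labels, F=float(F),
        df_between=df_between, df_within=df_within, p=float(p),
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
    )
    hsd = stats.tukey_hsd(*arrays)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            res.tukey.append((labels[a], labels[b], float(hsd.pvalue[a, b])))
    return res


def tukey_hsd(values, order=None) -> list[tuple[str, str, float]]:
    """Studentized-range adjusted p for every unordered group pair."""
    return anova_oneway(values, order=order).tukey


# ----------------------------------------------------------------------

def zone_summary(cwm_table: pd.DataFrame, ses_table: pd.DataFrame,
                 zone_order=None, unit: str = "cup",
                 ses_column: str = "ses_sd") -> dict:
    """The battery of life-zone ANOVAs on community metrics.

    Runs one ANOVA per (metric in {cwm, ses_range}) x taxon x trait
    present in the input tables (eight with both taxa and traits), using
    cup-level values pooled across sites and seasons as replicates
    (``unit='cup'``) or site means (``unit='site_mean'``).

    Returns ``{"anova": DataFrame, "tukey": DataFrame, "zone_stats":
    DataFrame, "results": list[AnovaResult]}``.
    """
    if unit not in ("cup", "site_mean"):
        raise InputError(f"unit must be 'cup' or 'site_mean', got {unit!r}")
    metric_tables = {"cwm": (cwm_table, "cwm"), "ses_range": (ses_table, ses_column)}
    anova_rows, tukey_rows, stat_rows, results = [], [], [], []
    for metric, (table, column) in metric_tables.items():
        if table is None or table.empty:
            warnings.warn(f"no data for metric {metric}; skipped", stacklevel=2)
            continue
        for (taxon, trait), sub in table.groupby(["taxon", "trait"], sort=True):
            if unit == "site_mean":
                sub = (sub.groupby(["life_zone", "site_id"], as_index=False)
                       [column].mean())
            pairs = list(zip(sub["life_zone"], sub[column]))
            response = f"{metric}_{trait}_{taxon}"
            try:
                res = anova_oneway(pairs, order=zone_order, response=response)
            except InputError as exc:
                warnings.warn(f"{response}: {exc}; skipped", stacklevel=2)
                continue
            results.append(res)
            anova_rows.append((metric, taxon, trait, res.F, res.df_between,
                               res.df_within, res.p))
            for a, b, padj in res.tukey:
                tukey_rows.append((metric, taxon, trait, a, b, padj))
            for zone in res.groups:
                stat_rows.append((metric, taxon, trait, zone,
                                  res.group_means[zone], res.group_sds[zone]))
    return {
        "anova": pd.DataFrame(anova_rows, columns=[
            "metric", "taxon", "trait", "F", "df1", "df2", "p"]),
        "tukey": pd.DataFrame(tukey_rows, columns=[
            "metric", "taxon", "trait", "zone_a", "zone_b", "p_adj"]),
        "zone_stats": pd.DataFrame(stat_rows, columns=[
            "metric", "taxon", "trait", "life_zone", "mean", "sd"]),
        "results": results,
    }


def intraspecific_trends(table: pd.DataFrame, min_zones: int = 3,
                         alpha: float = 0.05, zone_order=None,
                         traits=tuple(TRAIT_COLUMNS)) -> pd.DataFrame:
    """Within-species trait trends across life zones.

    Species qualify when present in at least ``min_zones`` zones with at
    least two individuals per zone.  For each qualifying species x trait a
    one-way ANOVA across zones is run; when p < ``alpha`` the direction is
    the sign of the slope of zone means against elevation rank (zones
    ordered low to high elevation), otherwise 'none'.
    """
    if zone_order is None:
        zone_order = list(pd.unique(table["life_zone"]))
    rows = []
    for (taxon, species), sub in table.groupby(["taxon", "species_id"], sort=True):
        counts = sub.groupby("life_zone").size()
        zones = [z for z in zone_order if counts.get(z, 0) >= 2]
        if len(zones) < min_zones:
            continue
        sub = sub[sub["life_zone"].isin(zones)]
        for trait in traits:
            col = trait_column(trait)
            try:
                res = anova_oneway(zip(sub["life_zone"], sub[col]), order=zones)
            except InputError:
                continue
            zone_means = [res.group_means[z] for z in zones]
            direction = "none"
            if res.p < alpha:
                slope = np.polyfit(np.arange(len(zones)), zone_means, 1)[0]
                direction = "+" if slope > 0 else "-"
            row = {"species_id": species, "taxon": taxon, "trait": trait}
            row.update({f"mean_{z}": m for z, m in zip(zones, zone_means)})
            row.update({"df": res.df_between, "F": res.F, "p": res.p,
                        "direction": direction})
            rows.append(row)
    if not rows:
        warnings.warn("no species qualify for the intraspecific analysis",
                      stacklevel=2)
        return pd.DataFrame(columns=["species_id", "taxon", "trait", "df",
                                     "F", "p", "direction"])
    return pd.DataFrame(rows)
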