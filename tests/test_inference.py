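"""Tests of the zone-level ANOVA/Tukey battery and intraspecific trends."""

import numpy as np
import pytest
from scipy import stats

import traitfilter as tf
from traitfilter.errors import InputError
from traitfilter.inference import anova_oneway, tukey_hsd

from conftest import make_table


def pairs(groups):
    return [(label, v) for label, values in groups.items() for v in values]


class TestAnova:
    def test_hand_computed_f_statistic(self):
        groups = {"a": [1, 2, 3], "b": [11, 12, 13], "c": [21, 22, 23]}
        res = anova_oneway(pairs(groups))
        # MS_between = 300, MS_within = 1
        assert res.F == pytest.approx(300.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.group_means == {"a": 2.0, "b": 12.0, "c": 22.0}

    def test_identical_groups_null(self):
        groups = {"a": [1, 2, 3], "b": [1, 2, 3]}
        res = anova_oneway(pairs(groups))
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(InputError, match="variance"):
            anova_oneway(pairs({"a": [5, 5], "b": [5, 5]}))

    def test_too_small_groups_rejected(self):
        with pytest.raises(InputError):
            anova_oneway(pairs({"a": [1], "b": [2, 3]}))
        with pytest.raises(InputError):
            anova_oneway(pairs({"a": [1, 2]}))

    def test_duplicating_data_keeps_means_increases_f(self):
        rng = np.random.default_rng(0)
        groups = {g: list(rng.normal(m, 1, 5)) for g, m in
                  [("a", 0), ("b", 1), ("c", 2)]}
        res = anova_oneway(pairs(groups))
        doubled = {g: v + v for g, v in groups.items()}
        res2 = anova_oneway(pairs(doubled))
        assert res2.group_means == pytest.approx(res.group_means)
        assert res2.df_within == 2 * res.df_within + 3
        assert res2.F > res.F

    def test_power_at_configured_zone_effect(self, default_bundle):
        """Zone darkness means of 35/35/78 are detected at p < 0.001."""
        anova = default_bundle.anova_table
        row = anova[(anova.metric == "cwm") & (anova.taxon == "bee")
                    & (anova.trait == "darkness")].iloc[0]
        assert row.p < 0.001

    def test_type_one_error_near_nominal(self):
        """Null zone ANOVA rejects at about the nominal 5% rate."""
        rng = np.random.default_rng(12)
        rejected = 0
        n_rep = 600
        for _ in range(n_rep):
            values = [("z1", v) for v in rng.normal(size=6)]
            values += [("z2", v) for v in rng.normal(size=6)]
            values += [("z3", v) for v in rng.normal(size=6)]
            rejected += anova_oneway(values).p < 0.05
        rate = rejected / n_rep
        assert 0.03 < rate < 0.07


class TestTukey:
    def test_identical_groups_all_near_one(self):
        groups = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        for _, _, p in tukey_hsd(pairs(groups)):
            assert p > 0.95

    def test_outlier_group_ordering(self):
        groups = {"a": [1, 2, 3], "b": [1.5, 2.5, 3.5], "c": [50, 51, 52]}
        ps = {frozenset((x, y)): p for x, y, p in tukey_hsd(pairs(groups))}
        assert ps[frozenset(("a", "c"))] < ps[frozenset(("a", "b"))]
        assert ps[frozenset(("b", "c"))] < ps[frozenset(("a", "b"))]

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(m, 1, 8) for g, m in
                  [("a", 0.0), ("b", 0.4), ("c", 1.0)]}
        adj = {frozenset((x, y)): p for x, y, p in tukey_hsd(pairs(groups))}
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            raw = stats.ttest_ind(groups[x], groups[y]).pvalue
            assert adj[frozenset((x, y))] >= raw - 1e-12


class TestZoneSummary:
    def test_default_run_yields_eight_anovas(self, default_bundle):
        anova = default_bundle.anova_table
        assert len(anova) == 8
        assert set(anova.metric) == {"cwm", "ses_range"}
        assert set(anova.taxon) == {"bee", "fly"}
        assert set(anova.trait) == {"volume", "darkness"}
        # Tukey covers all three zone pairs for each response
        assert len(default_bundle.tukey_table) == 8 * 3

    def test_no_filtering_no_zone_effect_on_bee_ses(self):
        """With filtering off and flat trait targets the bee sesRange ANOVA
        is typically null (majority of seeds give p > 0.05)."""
        cfg = tf.GeneratorConfig(n_bee_species=80, n_fly_species=10,
                                 n_bee_individuals=600, n_fly_individuals=10)
        cfg.filtering_strength = {"bee": (0, 0, 0), "fly": (0, 0, 0)}
        cfg.zone_trait_means = {
            t: {tr: tuple([v[0]] * 3) for tr, v in d.items()}
            for t, d in cfg.zone_trait_means.items()}
        # exchangeable zones: equal occupancy and abundance everywhere
        cfg.zone_occupancy = {"bee": (0.6, 0.6, 0.6), "fly": (0.6, 0.6, 0.6)}
        cfg.zone_abundance = {"bee": (1, 1, 1), "fly": (1, 1, 1)}
        ps = []
        for seed in range(5):
            bundle = tf.run_pipeline(cfg, seed=seed, B=200, taxa=("bee",),
                                     traits=("darkness",))
            anova = bundle.anova_table
            row = anova[(anova.metric == "ses_range")]
            ps.append(float(row.p.iloc[0]))
        assert np.median(ps) > 0.05

    def test_configured_truncation_recovered_as_strong_filter(self,
                                                              default_bundle):
        zs = default_bundle.zone_stats
        sf = zs[(zs.metric == "ses_range") & (zs.taxon == "bee")
                & (zs.trait == "darkness") & (zs.life_zone == "spruce_fir")]
        assert sf["mean"].iloc[0] < -1.96

    def test_site_mean_unit_reduces_df(self, default_bundle):
        summary = tf.zone_summary(default_bundle.cwm_table,
                                  default_bundle.ses_table, unit="site_mean")
        anova = summary["anova"]
        # 3 sites per zone, 3 zones -> df_within = 6 for every response
        assert (anova.df2 == 6).all()


class TestIntraspecificTrends:
    def test_species_in_two_zones_excluded(self):
        rows = []
        for zone in ("ponderosa", "mixed_conifer"):
            rows += [("bee", "sp1", zone, f"c_{zone}", 10, 40),
                     ("bee", "sp1", zone, f"c_{zone}", 12, 44)]
        table = make_table(rows)
        with pytest.warns(UserWarning):
            trends = tf.intraspecific_trends(table, min_zones=3)
        assert trends.empty

    def test_rising_darkness_flagged_positive(self):
        rng = np.random.default_rng(4)
        rows = []
        for zone, mean in [("ponderosa", 30), ("mixed_conifer", 60),
                           ("spruce_fir", 90)]:
            for d in rng.normal(mean, 2, size=8):
                rows.append(("bee", "sp1", zone, f"c_{zone}", 10.0, d))
        trends = tf.intraspecific_trends(
            make_table(rows), zone_order=["ponderosa", "mixed_conifer",
                                          "spruce_fir"])
        row = trends[trends.trait == "darkness"].iloc[0]
        assert row.p < 0.05
        assert row.direction == "+"
        assert row.df == 2

    def test_flat_means_direction_none(self):
        rng = np.random.default_rng(9)
        rows = []
        for zone in ("ponderosa", "mixed_conifer", "spruce_fir"):
            for d in rng.normal(50, 5, size=8):
                rows.append(("bee", "sp1", zone, f"c_{zone}", 10.0, d))
        trends = tf.intraspecific_trends(
            make_table(rows), zone_order=["ponderosa", "mixed_conifer",
                                          "spruce_fir"])
        assert (trends.direction == "none").all()

    def test_synthetic_dataset_recovers_rising_trends(self, default_table):
        """Comonotonic species draws + rising zone targets produce mostly
        '+' significant intraspecific directions in the default dataset."""
        trends = tf.intraspecific_trends(
            default_table, zone_order=["ponderosa", "mixed_conifer",
                                       "spruce_fir"])
        flagged = trends[trends.direction != "none"]
        assert len(trends) > 0
        if len(flagged) > 0:
            assert (flagged.direction == "+").mean() > 0.5
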