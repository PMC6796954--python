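"""Tests of the richness-conditioned null model and sesRange."""

import itertools

import numpy as np
import pandas as pd
import pytest

import traitfilter as tf
from traitfilter.errors import InputError, UndefinedSESError
from traitfilter.nullmodel import (CONSISTENT, STRONG_FILTER, WEAK_FILTER,
                                   NullDistribution, RegionalPool,
                                   build_null_distribution, classify_filtering,
                                   ses_range, ses_table)

from conftest import make_table


def brute_force_null(values, k):
    """Independent oracle: enumerate every k-subset with itertools."""
    ranges = [max(c) - min(c) for c in itertools.combinations(values, k)]
    return float(np.mean(ranges)), float(np.std(ranges))


class TestNullDistribution:
    def test_exhaustive_small_pool_matches_enumeration(self):
        pool = RegionalPool("bee", "darkness", [1, 2, 3, 4])
        nd = build_null_distribution(pool, k=2)
        assert nd.exhaustive
        assert nd.null_mean == pytest.approx(5 / 3)
        mean, sd = brute_force_null(pool.values, 2)
        assert nd.null_mean == pytest.approx(mean)
        assert nd.null_sd == pytest.approx(sd)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_exhaustive_matches_enumeration_for_random_pools(self, k):
        rng = np.random.default_rng(k)
        values = rng.uniform(0, 100, size=9)
        nd = build_null_distribution(RegionalPool("bee", "darkness", values), k)
        mean, sd = brute_force_null(values, k)
        assert nd.exhaustive
        assert nd.null_mean == pytest.approx(mean)
        assert nd.null_sd == pytest.approx(sd)

    def test_k_equal_pool_size_degenerate(self):
        pool = RegionalPool("bee", "darkness", [3.0, 9.0, 1.0])
        nd = build_null_distribution(pool, k=3)
        assert nd.null_mean == 8.0
        assert nd.null_sd == 0.0

    def test_constant_pool_all_ranges_zero(self):
        pool = RegionalPool("bee", "darkness", [7.0] * 6)
        nd = build_null_distribution(pool, k=3)
        assert np.all(nd.null_ranges == 0)
        assert nd.null_mean == 0.0

    def test_monte_carlo_converges_to_exhaustive(self):
        """Oracle equivalence: sampled null moments approach the exact ones
        within 3 standard errors as B grows."""
        rng = np.random.default_rng(10)
        values = rng.normal(50, 12, size=12)
        pool = RegionalPool("bee", "darkness", values)
        for k in (2, 4, 7):
            exact = build_null_distribution(pool, k)
            assert exact.exhaustive
            B = 4000
            mc = build_null_distribution(pool, k, B=B, rng=rng,
                                         exhaustive_cap=0)
            assert not mc.exhaustive
            se = exact.null_sd / np.sqrt(B)
            assert abs(mc.null_mean - exact.null_mean) < 3 * se
            assert mc.null_sd == pytest.approx(exact.null_sd, rel=0.1)

    def test_k_out_of_bounds(self):
        pool = RegionalPool("bee", "darkness", [1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            build_null_distribution(pool, k=1)
        with pytest.raises(InputError):
            build_null_distribution(pool, k=4)


class TestSESRange:
    def make_null(self, mean=10.0, sd=2.0):
        return NullDistribution("darkness", 4, 1000, np.array([mean]), None,
                                mean, sd, False)

    def test_centered_observation_is_null(self):
        res = ses_range(10.0, self.make_null())
        assert res.ses_paper == 0.0
        assert res.ses_sd == 0.0
        assert res.classification == CONSISTENT

    def test_two_sd_above_is_weak_filter(self):
        res = ses_range(14.0, self.make_null(), mode="sd")
        assert res.ses_sd == pytest.approx(2.0)
        assert res.significant
        assert res.classification == WEAK_FILTER

    def test_exhaustive_pool_paper_mode(self):
        pool = RegionalPool("bee", "darkness", [1, 2, 3, 4])
        nd = build_null_distribution(pool, k=2)
        res = ses_range(3.0, nd, mode="paper_mean")
        assert res.ses_paper == pytest.approx((3 - 5 / 3) / (5 / 3))
        assert res.ses_paper == pytest.approx(0.8)

    def test_monotone_in_observed_range(self):
        nd = self.make_null()
        values = [ses_range(x, nd).ses_sd for x in (2.0, 6.0, 10.0, 15.0)]
        assert values == sorted(values)
        assert len(set(values)) == len(values)

    def test_zero_denominator_raises(self):
        nd = NullDistribution("darkness", 3, 1, np.array([0.0]), None, 0.0,
                              0.0, True)
        with pytest.raises(UndefinedSESError, match="sd"):
            ses_range(1.0, nd, mode="sd")
        with pytest.raises(UndefinedSESError, match="mean"):
            ses_range(1.0, nd, mode="paper_mean")

    @pytest.mark.parametrize("value, expected", [
        (-2.5, STRONG_FILTER), (2.5, WEAK_FILTER), (0.3, CONSISTENT),
        (-1.96, STRONG_FILTER),
    ])
    def test_classification_rule(self, value, expected):
        res = ses_range(10.0 + 2.0 * value, self.make_null(), mode="sd")
        assert res.classification == expected
        assert classify_filtering(res) == expected


def _samples_from_pool(values, ks, rng):
    rows = []
    cup = 0
    for k in ks:
        idx = rng.choice(len(values), size=k, replace=False)
        for i in idx:
            rows.append(("bee", f"s{i}", "ponderosa", f"cup{cup}", 1.0,
                         values[i]))
        cup += 1
    return tf.group_samples(make_table(rows))


class TestSESTable:
    def test_null_assembly_centers_near_zero(self):
        rng = np.random.default_rng(21)
        values = rng.normal(60, 15, size=400)
        pool = RegionalPool("bee", "darkness", values)
        samples = _samples_from_pool(values, [5] * 150, rng)
        table = ses_table(samples, pool, "darkness", B=800, rng=rng)
        assert abs(table["ses_sd"].mean()) < 0.25

    def test_adversarial_narrow_samples_strongly_negative(self):
        rng = np.random.default_rng(3)
        values = np.sort(rng.normal(60, 15, size=200))
        # cups built from the tightest consecutive run of 6 values
        spread = values[5:] - values[:-5]
        start = int(np.argmin(spread))
        rows = [("bee", f"s{i}", "ponderosa", "cup0", 1.0, values[start + i])
                for i in range(6)]
        samples = tf.group_samples(make_table(rows))
        pool = RegionalPool("bee", "darkness", values)
        table = ses_table(samples, pool, "darkness", B=800, rng=rng)
        assert table["ses_sd"].iloc[0] < -2.0

    def test_single_eligible_sample(self):
        rng = np.random.default_rng(0)
        values = np.arange(30.0)
        pool = RegionalPool("bee", "darkness", values)
        rows = [("bee", "s1", "ponderosa", "cup0", 1.0, 5),
                ("bee", "s2", "ponderosa", "cup0", 1.0, 9),
                ("bee", "s3", "ponderosa", "cup1", 1.0, 9)]
        samples = tf.group_samples(make_table(rows))
        table = ses_table(samples, pool, "darkness", B=200, rng=rng)
        assert len(table) == 1  # the singleton cup is excluded

    def test_empty_eligible_set_warns(self):
        pool = RegionalPool("bee", "darkness", np.arange(10.0))
        rows = [("bee", "s1", "ponderosa", "cup0", 1.0, 5)]
        samples = tf.group_samples(make_table(rows))
        with pytest.warns(UserWarning, match="eligible"):
            table = ses_table(samples, pool, "darkness", B=100,
                              rng=np.random.default_rng(0))
        assert table.empty

    def test_taxon_mismatch_rejected(self):
        pool = RegionalPool("fly", "darkness", np.arange(10.0))
        rows = [("bee", "s1", "ponderosa", "cup0", 1.0, 5),
                ("bee", "s2", "ponderosa", "cup0", 1.0, 6)]
        samples = tf.group_samples(make_table(rows))
        with pytest.raises(InputError, match="taxon"):
            ses_table(samples, pool, "darkness", rng=np.random.default_rng(0))

    def test_seeded_determinism(self):
        rng_data = np.random.default_rng(8)
        values = rng_data.normal(60, 15, size=300)
        pool = RegionalPool("bee", "darkness", values)
        samples = _samples_from_pool(values, [3, 5, 5, 8, 2], rng_data)
        t1 = ses_table(samples, pool, "darkness", B=500,
                       rng=np.random.default_rng(99))
        t2 = ses_table(samples, pool, "darkness", B=500,
                       rng=np.random.default_rng(99))
        pd.testing.assert_frame_equal(t1, t2)
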