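"""Tests of vertical profiles, aggregation, one-way ANOVA and Duncan's
multiple range test (against independent brute-force decisions and frozen
studentized-range table values)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voxfpar.errors import InsufficientDataError
from voxfpar.stats import (aggregate, duncan_critical_ranges, duncan_mrt,
                           gradient_percent, groups_share_letter,
                           one_way_anova, stratum_gradient, vertical_profile)


class TestVerticalProfile:
    def test_constant_values(self):
        table = pd.DataFrame({"z": [1.0, 6.0, 11.0], "fpar_pred": 0.9})
        prof = vertical_profile(table, bin_width=5.0)
        assert (prof["mean"].dropna() == 0.9).all()
        assert prof["count"].sum() == 3

    def test_bin_mean_arithmetic(self):
        table = pd.DataFrame({"z": [1.0, 6.0, 7.0],
                              "fpar_pred": [0.8, 0.6, 1.0]})
        prof = vertical_profile(table, bin_width=5.0)
        assert prof["mean"].tolist() == pytest.approx([0.8, 0.8])

    def test_single_wide_bin_is_global_mean(self, rng):
        table = pd.DataFrame({"z": rng.uniform(0, 20, 100),
                              "fpar_pred": rng.uniform(0, 1, 100)})
        prof = vertical_profile(table, bin_width=50.0)
        assert len(prof) == 1
        assert prof["mean"].iloc[0] == pytest.approx(
            table["fpar_pred"].mean())

    def test_empty_bins_reported_missing(self):
        table = pd.DataFrame({"z": [1.0, 22.0], "fpar_pred": [0.5, 0.7]})
        prof = vertical_profile(table, bin_width=5.0)
        assert len(prof) == 5
        assert prof["mean"].isna().sum() == 3


class TestGradient:
    def test_worked_example(self):
        assert gradient_percent(0.882, 0.70) == pytest.approx(26.0, abs=1e-9)

    def test_equal_means_zero(self):
        assert gradient_percent(0.5, 0.5) == 0.0

    def test_zero_lower_mean_undefined(self):
        assert np.isnan(gradient_percent(0.5, 0.0))

    def test_stratum_table_helper(self):
        table = pd.DataFrame({"stratum": ["upper", "upper", "lower"],
                              "fpar": [0.9, 0.864, 0.7]})
        assert stratum_gradient(table) == pytest.approx(26.0, abs=1e-9)


class TestAggregate:
    def test_single_group_mean(self, rng):
        table = pd.DataFrame({"tree_id": 1, "z": rng.uniform(0, 20, 50),
                              "fpar_pred": rng.uniform(0, 1, 50)})
        out = aggregate(table, by=["tree_id"])
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(
            table["fpar_pred"].mean())

    def test_matches_brute_force_filtering(self, rng):
        table = pd.DataFrame({
            "tree_id": rng.integers(1, 6, 300),
            "stratum": rng.choice(["upper", "middle", "lower"], 300),
            "fpar_pred": rng.uniform(0, 1, 300),
        })
        out = aggregate(table, by=["tree_id", "stratum"])
        for row in out.itertuples():
            sub = table[(table["tree_id"] == row.tree_id)
                        & (table["stratum"] == row.stratum)]
            assert row.mean == pytest.approx(sub["fpar_pred"].mean(),
                                             abs=1e-12)
            assert row.count == len(sub)

    def test_mass_consistency(self, rng):
        table = pd.DataFrame({
            "tree_id": rng.integers(1, 9, 500),
            "fpar_pred": rng.uniform(0, 1, 500),
        })
        out = aggregate(table, by=["tree_id"])
        recombined = (out["mean"] * out["count"]).sum() / out["count"].sum()
        assert recombined == pytest.approx(table["fpar_pred"].mean(),
                                           abs=1e-12)

    def test_zone_exclusion_counted(self, rng):
        table = pd.DataFrame({"tree_id": 1, "z": [2.0, 8.0, 17.0, 22.0],
                              "fpar_pred": [0.1, 0.2, 0.3, 0.4]})
        zones = [("lower", 0.0, 5.0), ("middle", 10.0, 15.0),
                 ("upper", 15.0, 20.0)]
        out = aggregate(table, by=["zone"], zones=zones)
        assert out.attrs["n_excluded"] == 2  # 8.0 and 22.0 fall in no zone
        assert set(out["zone"]) == {"lower", "upper"}


class TestOneWayAnova:
    def test_hand_computed_example(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.f == pytest.approx(1.5, abs=1e-12)
        assert (res.df1, res.df2) == (1, 4)

    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f == 0.0

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(t ** 2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, n)
                  for m, n in [(0, 8), (0.3, 12), (0.7, 9), (0.1, 14)]]
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_zero_within_variance(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.f) and res.p == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova([[1, 2, 3]])


def test_studentized_range_quantiles_match_published_values():
    """Quantiles agree with distribution tables (frozen from R's qtukey)."""
    cases = [
        (0.95, 2, 10, 3.15106418), (0.95, 3, 10, 3.87677675),
        (0.95, 4, 20, 3.95829346), (0.95, 5, 30, 4.10207902),
        (0.95, 6, 60, 4.16316082), (0.99, 2, 12, 4.31977131),
        (0.99, 3, 24, 4.54556901), (0.99, 4, 40, 4.69513393),
    ]
    for p, k, df, expected in cases:
        got = sps.studentized_range.ppf(p, k, df)
        assert got == pytest.approx(expected, abs=1e-6)


def brute_force_duncan_nonsig(means_sorted, ranges):
    """Independent pairwise decision rule: a sorted pair (i, j) is
    homogeneous iff some containing span passes its own range test."""
    k = len(means_sorted)
    nonsig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i, k):
            for a in range(0, i + 1):
                for b in range(j, k):
                    if a == b:
                        continue
                    if (means_sorted[a] - means_sorted[b]) \
                            <= ranges[b - a - 1]:
                        nonsig[i, j] = True
    np.fill_diagonal(nonsig, True)
    return nonsig


class TestDuncan:
    def test_equal_means_single_letter(self):
        out = duncan_mrt([[1.0, 1.1, 0.9], [1.0, 1.1, 0.9],
                          [0.9, 1.0, 1.1]])
        assert out["letters"].nunique() == 1

    def test_two_groups_reduces_to_protected_range_test(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            a, b = r.normal(0, 1, 10), r.normal(0.8, 1, 10)
            out = duncan_mrt([a, b], labels=["a", "b"])
            res = one_way_anova([a, b])
            q = sps.studentized_range.ppf(0.95, 2, res.df2)
            crit = q * np.sqrt(res.ms_within / 10)
            significant = abs(a.mean() - b.mean()) > crit
            assert groups_share_letter(out, "a", "b") == (not significant)

    def test_clear_outlier_group_separated(self, rng):
        groups = [10 + 0.5 * rng.normal(size=8),
                  10.1 + 0.5 * rng.normal(size=8),
                  20 + 0.5 * rng.normal(size=8)]
        out = duncan_mrt(groups, labels=["low1", "low2", "high"])
        assert groups_share_letter(out, "low1", "low2")
        assert not groups_share_letter(out, "low1", "high")
        assert not groups_share_letter(out, "low2", "high")

    def test_zero_within_variance_separates_distinct_means(self):
        out = duncan_mrt([[1.0, 1.0], [2.0, 2.0], [2.0, 2.0]],
                         labels=["a", "b", "c"])
        assert not groups_share_letter(out, "a", "b")
        assert groups_share_letter(out, "b", "c")

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_brute_force_decisions(self, k):
        """Letter sharing reproduces the independent critical-range rule on
        random fixtures with 3..6 groups of unequal size."""
        for seed in range(10):
            r = np.random.default_rng(1000 * k + seed)
            sizes = r.integers(4, 9, k)
            means = r.uniform(0, 1.2, k)
            groups = [m + 0.25 * r.normal(size=n)
                      for m, n in zip(means, sizes)]
            labels = [f"g{i}" for i in range(k)]
            out = duncan_mrt(groups, labels=labels)
            anova = one_way_anova(groups)
            order = np.argsort(-anova.group_means, kind="stable")
            sorted_means = anova.group_means[order]
            n_h = k / np.sum(1.0 / anova.group_sizes[order])
            ranges = duncan_critical_ranges(k, anova.df2, anova.ms_within,
                                            n_h)
            expect = brute_force_duncan_nonsig(sorted_means, ranges)
            for i in range(k):
                for j in range(i + 1, k):
                    la = labels[order[i]]
                    lb = labels[order[j]]
                    assert groups_share_letter(out, la, lb) == expect[i, j], \
                        (seed, i, j, sorted_means, ranges)


def test_plot_helpers_write_files(tmp_path):
    from voxfpar.plots import plot_monthly_series, plot_vertical_profile
    profile = pd.DataFrame({"bin_low": [0, 5], "bin_high": [5, 10],
                            "mean": [0.2, 0.8], "count": [10, 5]})
    plot_vertical_profile(profile, tmp_path / "profile.png")
    series = pd.DataFrame({"date": ["2023-01-15", "2023-03-15"],
                           "mean": [0.95, 0.91]})
    plot_monthly_series(series, tmp_path / "series.png")
    assert (tmp_path / "profile.png").stat().st_size > 0
    assert (tmp_path / "series.png").stat().st_size > 0
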