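"""Two-group test battery: Mann-Whitney, Shapiro-Wilk, Levene, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from microwear.io import SpecimenRecord
from microwear.iso25178 import PARAMETER_NAMES
from microwear.stats import (
    compare_groups,
    levene,
    mann_whitney_u,
    shapiro_wilk,
    u_normal_pvalue,
)


class TestUNormalPvalue:
    @pytest.mark.parametrize(
        "U, n1, n2, printed",
        [
            (367, 32, 17, 0.046),
            (502, 34, 49, 0.002),
            (1093, 34, 49, 0.016),
            (1046, 34, 49, 0.049),
            (1129, 34, 49, 0.006),
        ],
    )
    def test_reported_worked_examples(self, U, n1, n2, printed):
        assert round(u_normal_pvalue(U, n1, n2), 3) == printed

    def test_null_mean_gives_p_one(self):
        assert u_normal_pvalue(272, 32, 17) == pytest.approx(1.0)

    def test_extreme_u_below_thousandth(self):
        assert u_normal_pvalue(1397, 34, 49) < 0.001

    def test_symmetric_about_null_mean(self):
        for d in (10, 50, 100):
            assert u_normal_pvalue(272 + d, 32, 17) == pytest.approx(
                u_normal_pvalue(272 - d, 32, 17), rel=1e-12
            )

    def test_monotone_in_deviation(self):
        ps = [u_normal_pvalue(272 + d, 32, 17) for d in range(0, 200, 10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            u_normal_pvalue(600, 32, 17)


class TestMannWhitney:
    def test_disjoint_groups_exact_enumeration(self):
        """a < b entirely: U = 0; only 2 of C(6,3) = 20 labelings are as
        extreme, so the exact two-sided P is 0.1."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)

    def test_u_sum_identity(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=5)
        u_ab = mann_whitney_u(a, b).statistic
        u_ba = mann_whitney_u(b, a).statistic
        assert u_ab + u_ba == 8 * 5

    def test_exact_matches_scipy_enumeration(self, rng):
        """Independent oracle: scipy's exact Mann-Whitney distribution."""
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            mine = mann_whitney_u(a, b, method="exact").p_two_sided
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_normal_approx_close_to_exact(self, rng):
        """The no-tie normal approximation tracks the exact two-sided P at
        n = 6/6 within the worst-case gap of the discrete null, which the
        enumeration oracle puts at 0.07."""
        from itertools import combinations

        ranks = np.arange(1, 13)
        us = np.array(
            [ranks[list(idx)].sum() - 21 for idx in combinations(range(12), 6)]
        )
        mu, sd = 18.0, np.sqrt(36 * 13 / 12)
        bound = max(
            abs(
                np.mean(np.abs(us - mu) >= abs(u - mu) - 1e-9)
                - min(1.0, 2 * sps.norm.sf(abs((u - mu) / sd)))
            )
            for u in range(37)
        )
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            p_apx = mann_whitney_u(a, b, method="normal_approx").p_two_sided
            p_exact = mann_whitney_u(a, b, method="exact").p_two_sided
            assert abs(p_apx - p_exact) <= bound + 1e-9

    def test_tie_corrected_matches_scipy_asymptotic(self, rng):
        data = rng.integers(0, 5, size=20).astype(float)
        a, b = data[:12], data[12:]
        mine = mann_whitney_u(a, b, method="normal_approx_tie_corrected")
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert mine.p_two_sided == pytest.approx(ref, abs=1e-10)
        assert mine.ties_present

    def test_balanced_u_gives_p_one(self):
        res = mann_whitney_u([1, 4], [2, 3])
        assert res.statistic == 2.0  # n1 n2 / 2
        assert res.p_two_sided == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


@settings(max_examples=30, deadline=None)
@given(
    n1=st.integers(2, 5),
    n2=st.integers(2, 5),
    seed=st.integers(0, 10_000),
)
def test_exact_p_equals_brute_force_enumeration(n1, n2, seed):
    """Oracle: direct enumeration over all labelings of pooled ranks."""
    from itertools import combinations

    rng = np.random.default_rng(seed)
    pooled = rng.normal(size=n1 + n2)
    a, b = pooled[:n1], pooled[n1:]
    res = mann_whitney_u(a, b, method="exact")
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2
    obs_dev = abs(res.statistic - mu)
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - mu) >= obs_dev - 1e-9
    assert res.p_two_sided == pytest.approx(hits / total, abs=1e-12)


class TestShapiroWilk:
    def test_three_points_give_w_one(self):
        res = shapiro_wilk([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(1.0, abs=1e-9)

    def test_calibrated_type_i_rate(self, rng):
        """Normal samples, n = 50: rejection at alpha 0.05 near nominal."""
        rejections = sum(
            shapiro_wilk(rng.normal(size=50)).p_two_sided < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_detects_extreme_outlier(self, rng):
        x = np.append(rng.normal(size=20), 15.0)
        assert shapiro_wilk(x).p_two_sided < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)


class TestLevene:
    def test_shift_invariance(self, rng):
        a = rng.normal(size=15)
        res = levene(a, a + 3.7)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_two_sided > 0.99

    def test_matches_anova_on_deviations_oracle(self, rng):
        """Classic Levene is a one-way ANOVA on |x - group mean|."""
        a = rng.normal(size=12)
        b = rng.normal(scale=2.0, size=17)
        res = levene(a, b, center="mean")
        da = np.abs(a - a.mean())
        db = np.abs(b - b.mean())
        f_ref, p_ref = sps.f_oneway(da, db)
        assert res.statistic == pytest.approx(f_ref, rel=1e-9)
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-9)

    def test_power_at_sigma_ratio_three(self, rng):
        hits = sum(
            levene(rng.normal(size=30), rng.normal(scale=3.0, size=30)).p_two_sided < 0.05
            for _ in range(200)
        )
        assert hits / 200 > 0.9

    def test_median_center_variant(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        res = levene(a, b, center="median")
        ref = sps.levene(a, b, center="median")
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.method == "levene_median"


def _records(values_by_group, group_field="facet", labels=("T2", "T3")):
    """Records with a single parameter 'Vm' taking the given values."""
    recs = []
    k = 0
    for label, values in zip(labels, values_by_group):
        for v in values:
            k += 1
            params = {name: 1.0 for name in PARAMETER_NAMES}
            params["Vm"] = float(v)
            recs.append(
                SpecimenRecord(
                    specimen_id=f"S{k}", locality="Kilpisjärvi", season="autumn",
                    facet=label, side="L", parameters=params,
                )
            )
    return recs


class TestCompareGroups:
    def test_row_per_analysed_parameter(self, rng):
        recs = _records([rng.normal(size=10), rng.normal(size=12)])
        table = compare_groups(recs, "facet_autumn")
        df = table.to_dataframe()
        assert len(df) == 18
        assert set(df["parameter"]) == set(PARAMETER_NAMES)

    def test_no_adjusted_p_column(self, rng):
        recs = _records([rng.normal(size=10), rng.normal(size=12)])
        df = compare_groups(recs, "facet_autumn").to_dataframe()
        assert not any("adjust" in c.lower() or "fdr" in c.lower() or "bonferroni" in c.lower()
                       for c in df.columns)

    def test_location_shift_detected(self, rng):
        recs = _records([rng.normal(size=20), rng.normal(loc=3.0, size=20)])
        table = compare_groups(recs, "facet_autumn", parameters=["Vm"])
        assert table.location["Vm"].p_two_sided < 0.001

    def test_season_dataset_descriptive_only(self, rng):
        recs = []
        for k in range(8):
            params = {name: float(k) for name in PARAMETER_NAMES}
            recs.append(
                SpecimenRecord(
                    specimen_id=f"S{k}", locality="Kilpisjärvi",
                    season="autumn" if k < 6 else "spring", facet="T3", side="L",
                    parameters=params,
                )
            )
        table = compare_groups(recs, "season_T3")
        assert table.location == {} and table.dispersion == {}
        df = table.to_dataframe()
        assert "median_autumn" in df.columns and "median_spring" in df.columns
        assert not any("P" in c for c in df.columns)

    def test_empty_group_rejected(self, rng):
        recs = _records([rng.normal(size=5), []])
        with pytest.raises(ValueError, match="empty"):
            compare_groups(recs, "facet_autumn")

    def test_missing_values_dropped_pairwise(self, rng):
        recs = _records([rng.normal(size=10), rng.normal(size=10)])
        recs[0].parameters["Vm"] = float("nan")
        table = compare_groups(recs, "facet_autumn", parameters=["Vm"])
        assert table.location["Vm"].n1 == 9
        assert table.location["Vm"].n2 == 10
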