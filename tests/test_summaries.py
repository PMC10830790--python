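"""Summary-statistic inference: ANOVA, Dunnett, Welch and pooled t-tests.

The central contract: every summary-path result equals the raw-data
result computed from samples carrying exactly the stated moments.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from isobolkit.summaries import (
    SummaryGroup,
    anova_from_summaries,
    dunnett_from_summaries,
    exact_moment_sample,
    pooled_t_from_summaries,
    welch_t,
    welch_t_from_summaries,
)

from conftest import PRINTED_F, PRINTED_T, ed50_summary_groups


def sg(label, mean, disp, kind, n, df=None):
    return SummaryGroup(label, mean, disp, kind, n, df)


class TestExactMomentSample:
    @pytest.mark.parametrize("mean, sd, n", [(0.0, 1.0, 2), (8.27, 4.8, 16), (-3.0, 0.2, 9)])
    def test_sample_has_exact_moments(self, mean, sd, n):
        x = exact_moment_sample(mean, sd, n)
        assert x.mean() == pytest.approx(mean, abs=1e-12)
        assert x.std(ddof=1) == pytest.approx(sd, rel=1e-12)


class TestAnova:
    def test_reproduces_reference_f_statistics(self, ed50_table):
        for drug, f_printed in PRINTED_F.items():
            res = anova_from_summaries(ed50_summary_groups(ed50_table, drug))
            assert res.f_stat == pytest.approx(f_printed, abs=0.01), drug
            assert res.df_between == 2

    def test_summary_path_equals_raw_path(self):
        groups = [
            sg("a", 8.27, 1.20, "SEM", 16),
            sg("b", 6.52, 0.88, "SEM", 16),
            sg("c", 3.38, 0.93, "SEM", 16),
        ]
        res = anova_from_summaries(groups)
        raw = stats.f_oneway(
            *(exact_moment_sample(g.mean, g.sd, g.n) for g in groups)
        )
        assert res.f_stat == pytest.approx(raw.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(raw.pvalue, abs=1e-10)

    def test_identical_means_give_zero_f(self):
        groups = [sg(l, 5.0, 1.0, "SD", 8) for l in "abc"]
        assert anova_from_summaries(groups).f_stat == 0.0

    @given(shift=st.floats(min_value=-1e3, max_value=1e3))
    def test_f_invariant_to_mean_shift(self, shift):
        base = [sg("a", 3.0, 1.0, "SD", 8), sg("b", 5.0, 2.0, "SD", 12), sg("c", 4.0, 1.5, "SD", 10)]
        shifted = [sg(g.label, g.mean + shift, g.dispersion, "SD", g.n) for g in base]
        f0 = anova_from_summaries(base).f_stat
        f1 = anova_from_summaries(shifted).f_stat
        assert f1 == pytest.approx(f0, rel=1e-9, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summaries([sg("a", 1.0, 1.0, "SD", 8)])


class TestDunnett:
    def test_reference_significance_pattern(self, ed50_table):
        """High-dose adjunct groups significant at 0.01, low-dose not at 0.05."""
        for drug in PRINTED_F:
            res = dunnett_from_summaries(
                ed50_summary_groups(ed50_table, drug), "vehicle",
                rng=np.random.default_rng(0),
            )
            assert res["IMP (50)"].significant_at_001, drug
            assert not res["IMP (25)"].significant_at_005, drug

    def test_t_statistics_match_scipy(self, ed50_table):
        groups = ed50_summary_groups(ed50_table, "LCM")
        res = dunnett_from_summaries(groups, "vehicle", rng=np.random.default_rng(0))
        scipy_res = stats.dunnett(
            *(
                exact_moment_sample(g.mean, g.sd, g.n)
                for g in groups
                if g.label != "vehicle"
            ),
            control=exact_moment_sample(
                groups[0].mean, groups[0].sd, groups[0].n
            ),
        )
        mine = [c.t_stat for c in res.comparisons]
        np.testing.assert_allclose(mine, scipy_res.statistic, atol=1e-10)

    def test_group_identical_to_control_is_null(self):
        groups = [
            sg("ctrl", 5.0, 1.0, "SD", 8),
            sg("same", 5.0, 1.0, "SD", 8),
            sg("far", 9.0, 1.0, "SD", 8),
        ]
        res = dunnett_from_summaries(groups, "ctrl", rng=np.random.default_rng(0))
        assert res["same"].t_stat == pytest.approx(0.0, abs=1e-12)
        assert not res["same"].significant_at_005

    def test_flags_monotone_in_mean_difference(self):
        def flags(delta):
            groups = [
                sg("ctrl", 5.0, 1.0, "SD", 8),
                sg("trt", 5.0 + delta, 1.0, "SD", 8),
            ]
            res = dunnett_from_summaries(groups, "ctrl", rng=np.random.default_rng(0))
            return abs(res["trt"].t_stat), res["trt"].p_value

        # widening difference: |t| grows, p shrinks
        t_small, p_small = flags(0.5)
        t_big, p_big = flags(3.0)
        assert t_big > t_small
        assert p_big < p_small

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dunnett_from_summaries(
                [sg("a", 1.0, 1.0, "SD", 8), sg("b", 2.0, 1.0, "SD", 8)], "nope"
            )

    def test_significance_levels_nested(self, ed50_table):
        for drug in PRINTED_F:
            res = dunnett_from_summaries(
                ed50_summary_groups(ed50_table, drug), "vehicle",
                rng=np.random.default_rng(0),
            )
            for c in res.comparisons:
                if c.significant_at_001:
                    assert c.significant_at_005


class TestWelch:
    def test_satterthwaite_example(self):
        res = welch_t(10.0, 1.0, 15.0, 7.0, 1.2, 15.0)
        # direct evaluation of the Welch-Satterthwaite formulas
        assert res.t_stat == pytest.approx(3.0 / np.sqrt(1 + 1.44), abs=1e-9)
        assert res.df == pytest.approx(2.44**2 / ((1 + 1.44**2) / 15), abs=1e-6)

    def test_identical_summaries_null(self):
        a = sg("a", 5.0, 1.0, "SEM", 8)
        res = welch_t_from_summaries(a, sg("b", 5.0, 1.0, "SEM", 8))
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_equal_sems_and_df_collapse_to_pooled_df(self):
        res = welch_t(4.0, 1.5, 7.0, 6.0, 1.5, 7.0)
        assert res.df == pytest.approx(14.0)

    def test_summary_path_equals_raw_path(self):
        a, b = sg("a", 10.0, 3.0, "SD", 12), sg("b", 8.0, 5.0, "SD", 20)
        res = welch_t_from_summaries(a, b)
        raw = stats.ttest_ind(
            exact_moment_sample(a.mean, a.sd, a.n),
            exact_moment_sample(b.mean, b.sd, b.n),
            equal_var=False,
        )
        assert res.t_stat == pytest.approx(raw.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(raw.pvalue, abs=1e-10)
        assert res.df == pytest.approx(raw.df, abs=1e-10)

    @given(
        m1=st.floats(-10, 10), m2=st.floats(-10, 10),
        s1=st.floats(0.1, 5), s2=st.floats(0.1, 5),
    )
    def test_antisymmetry(self, m1, m2, s1, s2):
        fwd = welch_t(m1, s1, 10.0, m2, s2, 14.0)
        rev = welch_t(m2, s2, 14.0, m1, s1, 10.0)
        assert fwd.t_stat == pytest.approx(-rev.t_stat, rel=1e-12, abs=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_nonpositive_sem_rejected(self):
        with pytest.raises(ValueError):
            welch_t(1.0, 0.0, 10.0, 2.0, 1.0, 10.0)


class TestPooled:
    def test_reproduces_reference_t_statistics(self, conc_table):
        for drug, t_printed in PRINTED_T.items():
            block = conc_table[conc_table.drug == drug]
            r1, r2 = block.itertuples()
            res = pooled_t_from_summaries(
                sg(r1.group, float(r1.mean), float(r1.sd), "SD", int(r1.n)),
                sg(r2.group, float(r2.mean), float(r2.sd), "SD", int(r2.n)),
            )
            assert abs(res.t_stat) == pytest.approx(t_printed, abs=0.005), drug
            assert res.df == 14

    def test_summary_path_equals_raw_path(self):
        a, b = sg("a", 0.252, 0.011, "SD", 8), sg("b", 0.248, 0.015, "SD", 8)
        res = pooled_t_from_summaries(a, b)
        raw = stats.ttest_ind(
            exact_moment_sample(a.mean, a.sd, a.n),
            exact_moment_sample(b.mean, b.sd, b.n),
            equal_var=True,
        )
        assert res.t_stat == pytest.approx(raw.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(raw.pvalue, abs=1e-10)

    def test_equal_means_null(self):
        res = pooled_t_from_summaries(
            sg("a", 5.0, 1.0, "SD", 8), sg("b", 5.0, 2.0, "SD", 8)
        )
        assert res.t_stat == 0.0


class TestSummaryGroup:
    def test_sem_sd_round_trip(self):
        g = sg("a", 8.27, 1.20, "SEM", 16)
        assert g.sd == pytest.approx(4.8)
        assert g.sem == pytest.approx(1.20)
        h = sg("b", 0.252, 0.011, "SD", 8)
        assert h.sem == pytest.approx(0.011 / np.sqrt(8))

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            sg("a", 1.0, 1.0, "sem?", 8)
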