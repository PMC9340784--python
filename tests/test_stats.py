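"""Group statistics, significance stars, and qPCR normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from gonadquant import (
    GroupSample,
    mean_sem,
    phase_frequencies,
    relative_expression,
    stars,
    t_test,
)
from gonadquant.stats import MITOSIS_PHASES, expression_table


class TestMeanSem:
    def test_constant_sample(self):
        assert mean_sem([5, 5, 5]) == (5.0, 0.0)

    def test_hand_computed(self):
        m, s = mean_sem([1, 2, 3])
        assert m == pytest.approx(2.0)
        assert s == pytest.approx(1.0 / math.sqrt(3), abs=1e-4)  # 0.5774

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_sem([4.2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_sem([])


class TestTTest:
    def test_identical_groups(self):
        g = GroupSample(("2n", 1), (1.0, 2.0, 3.0))
        res = t_test(g, g)
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        res = t_test(GroupSample(("2n", 1), (1, 2, 3)), GroupSample(("3n_alpha", 1), (2, 3, 4)))
        assert res.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.degrees_of_freedom == 4
        assert res.p_value == pytest.approx(0.2879, abs=1e-3)

    def test_zero_variance_convention(self):
        res = t_test(GroupSample(("a", 0), (0.0, 0.0)), GroupSample(("b", 0), (0.0, 0.0)))
        assert res.degenerate_flag
        assert res.p_value == 1.0

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            t_test(GroupSample(("a", 0), (1.0,)), GroupSample(("b", 0), (1.0, 2.0)))

    def test_matches_scipy_on_random_pairs(self):
        """Independent oracle: scipy's pooled two-sample t on 100 random pairs."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=nb)
            res = t_test(GroupSample(("a", 0), tuple(a)), GroupSample(("b", 0), tuple(b)))
            t_ref, p_ref = sstats.ttest_ind(a, b, equal_var=True)
            assert res.t_statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_welch_option(self):
        a = GroupSample(("a", 0), (1.0, 2.0, 3.0, 4.0))
        b = GroupSample(("b", 0), (10.0, 30.0))
        res = t_test(a, b, welch=True)
        t_ref, p_ref = sstats.ttest_ind(np.array(a.values), np.array(b.values), equal_var=False)
        assert res.t_statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.00005, "****"),
            (0.0001, "***"),
            (0.0004, "***"),
            (0.0005, "**"),
            (0.0007, "**"),
            (0.001, "*"),
            (0.04, "*"),
            (0.05, "ns"),
            (0.2, "ns"),
            (1.0, "ns"),
            (0.0, "****"),
        ],
    )
    def test_threshold_mapping(self, p, expected):
        assert stars(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_invalid_p(self, p):
        with pytest.raises(ValueError):
            stars(p)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_step_function(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert len(stars(lo).replace("ns", "")) >= len(stars(hi).replace("ns", ""))


class TestRelativeExpression:
    def test_zero_deviation(self):
        assert relative_expression(20.0, 20.0) == 1.0

    def test_one_cycle_halving(self):
        assert relative_expression(21.0, 20.0) == 0.5

    def test_doubling_per_cycle(self):
        assert relative_expression(18.0, 20.0) == 4.0

    @given(st.floats(min_value=5, max_value=35), st.floats(min_value=-10, max_value=10))
    @settings(max_examples=100, derandomize=True)
    def test_reciprocal_identity(self, x, k):
        prod = relative_expression(x, x + k) * relative_expression(x + k, x)
        assert prod == pytest.approx(1.0, rel=1e-12)

    def test_ddct_calibrator(self):
        # dCt 2 against a calibrator dCt of 2 gives unity
        assert relative_expression(22.0, 20.0, calibrator_delta=2.0) == 1.0

    def test_expression_table(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2", "s2"],
                "gene": ["EF1a", "CDC20", "EF1a", "CDC20"],
                "ct": [20.0, 22.0, 21.0, 21.0],
            }
        )
        recs = expression_table(df)
        assert len(recs) == 2
        assert recs[0].relative_expression == pytest.approx(0.25)
        assert recs[1].relative_expression == pytest.approx(1.0)

    def test_missing_reference_gene(self):
        df = pd.DataFrame({"sample_id": ["s1"], "gene": ["CDC20"], "ct": [22.0]})
        with pytest.raises(ValueError, match="reference gene"):
            expression_table(df)


class TestAdjustPvalues:
    def test_none_is_identity(self):
        from gonadquant.stats import adjust_pvalues

        assert adjust_pvalues([0.01, 0.2]) == [0.01, 0.2]

    def test_bonferroni_and_bh(self):
        from gonadquant.stats import adjust_pvalues

        ps = [0.01, 0.02, 0.5]
        assert adjust_pvalues(ps, "bonferroni") == pytest.approx([0.03, 0.06, 1.0])
        bh = adjust_pvalues(ps, "bh")
        ref = sstats.false_discovery_control(ps, method="bh")
        assert bh == pytest.approx(list(ref))
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm-sidak-nonsense")


class TestPhaseFrequencies:
    def test_reported_scale_example(self):
        # late-prophase-dominated tally, as in early-stage diploid counts
        counts = {"late prophase": 63, "prometaphase/metaphase": 30, "anaphase": 7}
        freqs = phase_frequencies(counts)
        assert freqs["late prophase"] == pytest.approx(63.0)
        assert freqs["prometaphase/metaphase"] == pytest.approx(30.0)
        assert freqs["G2"] == 0.0

    def test_single_phase(self):
        freqs = phase_frequencies({"anaphase": 5})
        assert freqs["anaphase"] == 100.0

    def test_uniform_counts(self):
        freqs = phase_frequencies({p: 1 for p in MITOSIS_PHASES})
        assert freqs["G2"] == pytest.approx(100 / 6, abs=0.01)

    @pytest.mark.parametrize(
        "counts", [{}, {"G2": 0}, {"nonsense": 3}, {"G2": -1, "anaphase": 2}]
    )
    def test_invalid_inputs(self, counts):
        with pytest.raises(ValueError):
            phase_frequencies(counts)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=6, max_size=6))
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_hundred(self, values):
        counts = dict(zip(MITOSIS_PHASES, values))
        if sum(values) == 0:
            with pytest.raises(ValueError):
                phase_frequencies(counts)
        else:
            assert sum(phase_frequencies(counts).values()) == pytest.approx(100.0, abs=0.01)
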