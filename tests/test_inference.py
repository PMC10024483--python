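"""t-tests, mixed ANOVA, effect sizes, percent change and power analysis."""

import numpy as np
import pandas as pd
import pytest

import sprintfv as s
from sprintfv.errors import (
    DegenerateStatisticError,
    IncompleteDesignError,
    InvalidInputError,
)


def _frame(y, n1, n2, groups=("A", "B")):
    n = n1 + n2
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), 2),
        "group": np.repeat([groups[0]] * n1 + [groups[1]] * n2, 2),
        "session": ["pre", "post"] * n,
        "value": np.asarray(y).flatten(),
    })


def brute_force_split_plot(y, n1):
    """Independent sums-of-squares oracle: explicit loops over the design cells."""
    y = np.asarray(y, float)
    n, m = y.shape
    labels = np.array([0] * n1 + [1] * (n - n1))
    grand = y.mean()
    ss_group = ss_eb = ss_time = ss_int = ss_ew = 0.0
    time_means = [y[:, j].mean() for j in range(m)]
    for g in (0, 1):
        rows = y[labels == g]
        gm = rows.mean()
        ss_group += m * len(rows) * (gm - grand) ** 2
        for r in rows:
            ss_eb += m * (r.mean() - gm) ** 2
        for j in range(m):
            cell = rows[:, j].mean()
            ss_int += len(rows) * (cell - gm - time_means[j] + grand) ** 2
            for r in rows:
                ss_ew += (r[j] - cell - r.mean() + gm) ** 2
    for j in range(m):
        ss_time += n * (time_means[j] - grand) ** 2
    df = {"group": 1, "eb": n - 2, "time": m - 1, "int": m - 1, "ew": (n - 2) * (m - 1)}
    f_group = (ss_group / df["group"]) / (ss_eb / df["eb"])
    f_time = (ss_time / df["time"]) / (ss_ew / df["ew"])
    f_int = (ss_int / df["int"]) / (ss_ew / df["ew"])
    return f_group, f_time, f_int


class TestIndependentT:
    def test_identical_groups(self):
        t, p = s.independent_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, p = s.independent_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.288, abs=1e-3)

    def test_translation_invariance(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, _ = s.independent_t(a, b)
        t2, _ = s.independent_t(a + 7.3, b + 7.3)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            s.independent_t([1, 1, 1], [1, 1, 1])


class TestMixedAnova:
    def test_equal_change_scores_give_zero_interaction(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.column_stack([pre, pre + 0.5])
        an = s.mixed_anova_2x2(_frame(y, 3, 3))
        assert an.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_toy_dataset_matches_brute_force(self):
        y = np.array([[1.0, 2.0], [2.0, 2.5], [3.0, 5.0], [4.0, 4.5]])
        an = s.mixed_anova_2x2(_frame(y, 2, 2))
        fg, ft, fi = brute_force_split_plot(y, 2)
        assert an.loc["group", "F"] == pytest.approx(fg, rel=1e-10)
        assert an.loc["time", "F"] == pytest.approx(ft, rel=1e-10)
        assert an.loc["interaction", "F"] == pytest.approx(fi, rel=1e-10)

    def test_unbalanced_simulated_frame_matches_brute_force(self, rng):
        y = rng.normal(0, 1, (22, 2))
        y[:14, 1] += 0.4
        an = s.mixed_anova_2x2(_frame(y, 14, 8))
        fg, ft, fi = brute_force_split_plot(y, 14)
        for name, ref in [("group", fg), ("time", ft), ("interaction", fi)]:
            assert an.loc[name, "F"] == pytest.approx(ref, rel=1e-10)

    def test_interaction_equals_squared_t_on_change_scores(self, rng):
        y = rng.normal(0, 1, (22, 2))
        d = y[:, 1] - y[:, 0]
        t, p_t = s.independent_t(d[:14], d[14:])
        an = s.mixed_anova_2x2(_frame(y, 14, 8))
        assert an.loc["interaction", "F"] == pytest.approx(t**2, rel=1e-10)
        assert an.loc["interaction", "p"] == pytest.approx(p_t, rel=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (22, 2))
        y[:14] += 0.3
        df = _frame(y, 14, 8)
        an = s.mixed_anova_2x2(df)
        ref = pg.mixed_anova(df, dv="value", within="session",
                             subject="subject", between="group").set_index("Source")
        assert an.loc["group", "F"] == pytest.approx(float(ref.loc["group", "F"]), rel=1e-9)
        assert an.loc["time", "F"] == pytest.approx(float(ref.loc["session", "F"]), rel=1e-9)
        assert an.loc["interaction", "F"] == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-9)

    def test_sum_of_squares_conserved(self, rng):
        y = rng.normal(0, 1, (22, 2))
        an = s.mixed_anova_2x2(_frame(y, 14, 8))
        subj_means = y.mean(axis=1)
        ss_subj = 2 * ((subj_means - y.mean()) ** 2).sum()
        ss_total = ((y - y.mean()) ** 2).sum()
        parts = an.loc[["time", "interaction"], "ss"].sum() + an.loc["error_within", "ss"]
        between = an.loc["group", "ss"] + an.loc["error_between", "ss"]
        assert between == pytest.approx(ss_subj, rel=1e-8)
        assert parts + ss_subj == pytest.approx(ss_total, rel=1e-8)

    def test_missing_session_raises(self):
        df = _frame(np.ones((4, 2)), 2, 2).drop(index=[1])
        with pytest.raises(IncompleteDesignError):
            s.mixed_anova_2x2(df)


class TestPairedChange:
    def test_constant_shift_is_degenerate_with_exact_change(self):
        with pytest.raises(DegenerateStatisticError) as exc:
            s.paired_change_test([4.0, 4.1, 4.2], [3.9, 4.0, 4.1])
        assert exc.value.detail["exact_change"] == pytest.approx(-0.1)

    def test_no_change_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            s.paired_change_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_monte_carlo_recovery_of_standardized_change(self, rng):
        """True within-group standardized change 0.74 recovered within 0.1."""
        ds = []
        for _ in range(1000):
            pre = rng.normal(5.18, 0.49, 14)
            post = pre + rng.normal(0.74 * 0.49, 0.25, 14)
            _, es = s.paired_change_test(pre, post)
            ds.append(es.d)
        assert np.mean(ds) == pytest.approx(0.74, abs=0.1)


class TestEffectSize:
    def test_equal_spread_two_sd_gap(self, rng):
        a = rng.normal(12, 2, 4000)
        b = rng.normal(10, 2, 4000)
        assert s.cohens_d_pooled(a, b).d == pytest.approx(1.0, abs=0.08)

    def test_summary_formula(self):
        es = s.cohens_d_from_summary(5.76, 0.84, 14, 5.18, 0.49, 14)
        assert es.d == pytest.approx(0.84, abs=0.005)
        assert es.cl95[0] < es.d < es.cl95[1]

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert s.cohens_d_pooled(a, b).d == pytest.approx(-s.cohens_d_pooled(b, a).d)

    @pytest.mark.parametrize(
        "d,label",
        [(0.74, "moderate"), (0.15, "trivial"), (1.20, "large"), (-0.65, "moderate"),
         (0.20, "small"), (2.00, "large"), (2.01, "extremely large")],
    )
    def test_banding(self, d, label):
        assert s.label_effect_size(d) == label


class TestPercentChange:
    def test_uniform_multiplicative_change(self, rng):
        pre = rng.normal(5.2, 0.5, 14)
        mean, sd = s.percent_change(pre, 1.1119 * pre)
        assert mean == pytest.approx(11.19, abs=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_no_change(self):
        assert s.percent_change([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_single_subject(self):
        mean, _ = s.percent_change([4.05], [3.94])
        assert mean == pytest.approx(-2.72, abs=0.005)

    def test_zero_pre_raises(self):
        with pytest.raises(InvalidInputError):
            s.percent_change([0.0, 1.0], [1.0, 1.0])


class TestPower:
    def test_required_sample_size_reference_design(self):
        assert s.required_sample_size(s.PowerSpec()) == 24

    def test_posthoc_power_at_twenty_two(self):
        assert round(s.achieved_power(s.PowerSpec(), 22), 2) == 0.76

    def test_null_effect_power_equals_alpha(self):
        spec = s.PowerSpec(effect_size_f=0.0)
        assert s.achieved_power(spec, 30) == pytest.approx(0.05)

    def test_monotone_in_n_f_rho(self):
        base = s.PowerSpec()
        powers = [s.achieved_power(base, n) for n in range(10, 60, 5)]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert s.achieved_power(s.PowerSpec(effect_size_f=0.4), 22) > s.achieved_power(base, 22)
        assert s.achieved_power(s.PowerSpec(corr_rho=0.7), 22) > s.achieved_power(base, 22)

    def test_required_n_is_right_inverse_of_power(self):
        spec = s.PowerSpec()
        for target in (0.5, 0.8, 0.9):
            n = s.required_sample_size(spec, target)
            assert s.achieved_power(spec, n) >= target
            assert s.achieved_power(spec, n - 1) < target

    def test_invalid_specs(self):
        with pytest.raises(InvalidInputError):
            s.PowerSpec(corr_rho=1.0)
        with pytest.raises(InvalidInputError):
            s.required_sample_size(s.PowerSpec(effect_size_f=0.0))
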