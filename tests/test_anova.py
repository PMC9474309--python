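"""One-way / two-way ANOVA, Tukey HSD, and the windowing layer.

Cross-checks use independent references: scipy.stats.f_oneway and
scipy.stats.tukey_hsd for the one-way layer, statsmodels OLS anova_lm for
the two-way decomposition.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssrscan import (
    DegenerateDataError,
    GenomeSequence,
    GroupedObservations,
    UnbalancedDesignError,
    f_tail_probability,
    naive_find_occurrences,
    one_way_anova,
    tukey_hsd,
    two_way_anova,
    windowed_counts,
)
from ssrscan.anova import f_critical_value


def grouped(*arrays, labels=None):
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    return GroupedObservations(tuple(labels), tuple(np.asarray(a, float) for a in arrays))


# ------------------------------------------------------------- one-way


def test_one_way_hand_example():
    """{1,2,3} vs {4,5,6}: SSB=13.5, SSW=4, df=(1,4), F=13.5 by direct
    evaluation of the sum-of-squares decomposition."""
    res = one_way_anova(grouped([1, 2, 3], [4, 5, 6]))
    assert res.ss_between == pytest.approx(13.5)
    assert res.df_between == 1
    assert res.ss_within == pytest.approx(4.0)
    assert res.df_within == 4
    assert res.ms_between == pytest.approx(13.5)
    assert res.ms_within == pytest.approx(1.0)
    assert res.f_statistic == pytest.approx(13.5)
    assert res.p_value == pytest.approx(stats.f.sf(13.5, 1, 4))


def test_one_way_equal_group_means():
    res = one_way_anova(grouped([1, 2, 3], [1, 2, 3]))
    assert res.ss_between == pytest.approx(0.0)
    assert res.f_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert not res.reject_null


def test_one_way_degenerate_zero_within_variance():
    with pytest.raises(DegenerateDataError) as err:
        one_way_anova(grouped([5, 5, 5], [5, 5, 5], labels=["a", "b"]))
    assert "a" in str(err.value) and "b" in str(err.value)


def test_one_way_requires_two_groups():
    with pytest.raises(ValueError):
        GroupedObservations(("only",), (np.array([1.0, 2.0]),))


def test_one_way_agrees_with_scipy_reference(rng):
    for _ in range(50):
        k = int(rng.integers(2, 8))
        arrays = [rng.normal(size=rng.integers(3, 12)) for _ in range(k)]
        res = one_way_anova(grouped(*arrays))
        f_ref, p_ref = stats.f_oneway(*arrays)
        assert res.f_statistic == pytest.approx(f_ref, abs=1e-8)
        assert res.p_value == pytest.approx(p_ref, abs=1e-8)


def test_sum_of_squares_partition(rng):
    """SS_between + SS_within recovers the total sum of squares."""
    for _ in range(50):
        arrays = [rng.normal(size=rng.integers(2, 10)) for _ in range(4)]
        res = one_way_anova(grouped(*arrays))
        pooled = np.concatenate(arrays)
        ss_total = ((pooled - pooled.mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(
            ss_total, rel=1e-9
        )


def test_paper_decision_rule_is_inverted():
    """The compatibility rule rejects when F < F_critical — the opposite of
    the standard test — and must disagree with it on a clear effect."""
    strong = grouped([0, 0.1, -0.1], [10, 10.1, 9.9])
    std = one_way_anova(strong, decision_rule="standard")
    pap = one_way_anova(strong, decision_rule="paper")
    assert std.reject_null and not pap.reject_null
    null = grouped([0, 1, -1], [0.2, 1.1, -0.9])
    assert not one_way_anova(null, decision_rule="standard").reject_null
    assert one_way_anova(null, decision_rule="paper").reject_null


# -------------------------------------------------------------- F tail


def test_f_tail_at_zero_is_one():
    assert f_tail_probability(0.0, 3, 10) == pytest.approx(1.0)


def test_f_tail_t_distribution_identity():
    """For df1=1, P(F >= f) equals the two-sided t tail at sqrt(f)."""
    f, d = 4.0, 10
    expected = 2 * stats.t.sf(np.sqrt(f), d)
    assert f_tail_probability(f, 1, d) == pytest.approx(expected, rel=1e-12)


def test_f_tail_monotone_decreasing():
    vals = [f_tail_probability(f, 4, 20) for f in (0, 0.5, 1, 2, 5, 50, 1e6)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-10


def test_f_tail_rejects_bad_df():
    with pytest.raises(ValueError):
        f_tail_probability(1.0, 0, 5)
    with pytest.raises(ValueError):
        f_critical_value(0.05, 1, 0)


# -------------------------------------------------------------- two-way


def test_two_way_all_equal_is_degenerate():
    y = [7.0] * 8
    a = ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"]
    b = ["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"]
    with pytest.raises(DegenerateDataError):
        two_way_anova(y, a, b)


def test_two_way_matches_statsmodels_reference(rng):
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.formula.api import ols

    a_levels, b_levels, r = 3, 4, 3
    rows = []
    for i in range(a_levels):
        for j in range(b_levels):
            for _ in range(r):
                rows.append({
                    "a": f"a{i}", "b": f"b{j}",
                    "y": i * 1.5 - j * 0.7 + (i == j) * 0.9 + rng.normal(),
                })
    df = pd.DataFrame(rows)
    res = two_way_anova(df["y"], df["a"], df["b"], factor_names=("a", "b"))
    fit = ols("y ~ C(a) * C(b)", data=df).fit()
    ref = sm.stats.anova_lm(fit, typ=2)
    for name, key in [("a", "C(a)"), ("b", "C(b)"), ("interaction", "C(a):C(b)")]:
        eff = res.effect(name)
        assert eff.ss == pytest.approx(ref.loc[key, "sum_sq"], rel=1e-8)
        assert eff.df == int(ref.loc[key, "df"])
        assert eff.f_statistic == pytest.approx(ref.loc[key, "F"], rel=1e-8)
        assert eff.p_value == pytest.approx(ref.loc[key, "PR(>F)"], abs=1e-8)
    assert res.residual_ss == pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-8)
    assert res.residual_df == int(ref.loc["Residual", "df"])


def test_two_way_partition_of_total_ss(rng):
    y = rng.normal(size=2 * 3 * 4)
    a = np.repeat(["a1", "a2"], 12)
    b = np.tile(np.repeat(["b1", "b2", "b3"], 4), 2)
    res = two_way_anova(y, a, b)
    parts = sum(e.ss for e in res.effects) + res.residual_ss
    assert parts == pytest.approx(res.ss_total, rel=1e-9)


def test_two_way_single_replicate_additive():
    # 3x2, one observation per cell: additive model, residual df = (3-1)(2-1)
    y = [1.0, 2.0, 2.5, 3.9, 4.2, 5.6]
    a = ["a1", "a1", "a2", "a2", "a3", "a3"]
    b = ["b1", "b2", "b1", "b2", "b1", "b2"]
    res = two_way_anova(y, a, b)
    assert [e.name for e in res.effects] == ["factor_a", "factor_b"]
    assert res.residual_df == 2


def test_two_way_rejects_unbalanced():
    y = [1.0, 2.0, 3.0, 4.0, 5.0]
    a = ["a1", "a1", "a1", "a2", "a2"]
    b = ["b1", "b2", "b2", "b1", "b2"]
    with pytest.raises(UnbalancedDesignError):
        two_way_anova(y, a, b)


# ---------------------------------------------------------------- Tukey


def test_tukey_identical_groups_do_not_reject():
    comps = tukey_hsd(grouped([1, 2, 3], [1, 2, 3]))
    (c,) = comps
    assert c.meandiff == pytest.approx(0.0)
    assert c.lower < 0 < c.upper
    assert not c.reject


def test_tukey_reject_iff_interval_excludes_zero(rng):
    for _ in range(30):
        arrays = [rng.normal(loc=rng.normal(scale=2), size=8) for _ in range(4)]
        for c in tukey_hsd(grouped(*arrays)):
            assert c.lower <= c.meandiff <= c.upper
            assert c.reject == (c.lower > 0 or c.upper < 0)


def test_tukey_one_shifted_group_flags_its_pairs(rng):
    a = rng.normal(0, 1, size=12)
    b = rng.normal(0, 1, size=12)
    c = rng.normal(25, 1, size=12)  # shift >> noise
    comps = tukey_hsd(grouped(a, b, c, labels=["a", "b", "c"]))
    rejected = {frozenset((x.group_a, x.group_b)) for x in comps if x.reject}
    assert rejected == {frozenset(("a", "c")), frozenset(("b", "c"))}


def test_tukey_agrees_with_scipy_reference(rng):
    for _ in range(20):
        arrays = [rng.normal(loc=rng.normal(), size=9) for _ in range(3)]
        comps = tukey_hsd(grouped(*arrays))
        ref = stats.tukey_hsd(*arrays)
        ci = ref.confidence_interval(0.95)
        for comp in comps:
            i = int(comp.group_a[1:])
            j = int(comp.group_b[1:])
            # scipy statistic[i, j] is mean_i - mean_j = -meandiff
            assert comp.meandiff == pytest.approx(-ref.statistic[i, j], abs=1e-10)
            assert comp.lower == pytest.approx(ci.low[j, i], abs=1e-8)
            assert comp.upper == pytest.approx(ci.high[j, i], abs=1e-8)


def test_tukey_anova_null_coupling(rng):
    """On null data, datasets with no Tukey rejection rarely have a
    significant one-way F test (statistical sanity coupling)."""
    agree = 0
    no_tukey = 0
    for _ in range(400):
        data = grouped(*[rng.normal(size=8) for _ in range(4)])
        comps = tukey_hsd(data, family_alpha=0.05)
        if not any(c.reject for c in comps):
            no_tukey += 1
            if one_way_anova(data, alpha=0.05).p_value > 0.05:
                agree += 1
    assert no_tukey > 0
    assert agree / no_tukey >= 0.95


def test_power_monotone_in_shift(rng):
    """Rejection rate is non-decreasing in the planted mean shift."""
    rates = []
    for shift in (0.0, 0.8, 2.5):
        rej = 0
        reps = 200
        child = np.random.default_rng(1234)  # common random numbers
        for _ in range(reps):
            base = [child.normal(size=8) for _ in range(3)]
            base[0] = base[0] + shift
            if one_way_anova(grouped(*base)).reject_null:
                rej += 1
        rates.append(rej / reps)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[0] < 0.15 and rates[2] > 0.9


# ------------------------------------------------------------ windowing


def test_windowed_counts_partition(rng):
    text = "".join(rng.choice(list("ACGT"), size=10_000))
    g = GenomeSequence("g", "", text)
    wc = windowed_counts(g, ["TAGA"], 1000)
    assert wc.shape == (1, 10)
    total = len(naive_find_occurrences(text, "TAGA"))
    assert wc.loc["TAGA"].sum() == total  # no partial window here


def test_windowed_counts_boundary_start_goes_to_containing_window():
    # occurrence starting exactly at the window boundary belongs to window 1
    text = "C" * 50 + "TAGA" + "C" * 46
    g = GenomeSequence("g", "", text)
    wc = windowed_counts(g, ["TAGA"], 50)
    assert wc.loc["TAGA", 0] == 0
    assert wc.loc["TAGA", 1] == 1


def test_windowed_counts_drops_trailing_partial_window():
    text = "C" * 100 + "TAGAG"  # occurrence at 100, inside the dropped tail
    g = GenomeSequence("g", "", text)
    wc = windowed_counts(g, ["TAGA"], 50)
    assert wc.shape[1] == 2
    assert wc.to_numpy().sum() == 0


def test_windowed_counts_validates_window_size():
    g = GenomeSequence("g", "", "ACGT" * 30)
    with pytest.raises(ValueError):
        windowed_counts(g, ["TAGA"], 39)  # < 10x motif length
    with pytest.raises(ValueError):
        windowed_counts(g, ["TAGA"], 1000)  # larger than the sequence
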