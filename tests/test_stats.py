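"""Detection rates, Fisher's exact test, RM-ANOVA, compact letter display."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from swirseg import (
    detection_rates,
    fisher_exact,
    letter_groups,
    rm_anova,
    round_half_up,
)
from swirseg.stats import (
    TABLE_COLUMNS,
    complete_cases,
    compare_measure,
    mixed_effects_pairwise,
)


def _table(rows):
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _calls_table(method_counts):
    """Build a table with k detections out of n for each method (opposing)."""
    rows = []
    for method, (k, n) in method_counts.items():
        for i in range(n):
            rows.append((i + 1, "opposing", method, i < k, np.nan, np.nan))
    return _table(rows)


# ------------------------------------------------------------------ rates

def test_rates_reproduce_printed_rounding():
    table = _calls_table({"radiograph": (11, 29), "swir_r": (27, 29),
                          "visual_before": (0, 29)})
    rates = {r.method: r.rate for r in detection_rates(table)
             if r.group == "opposing"}
    assert rates["radiograph"] == 0.38
    assert rates["swir_r"] == 0.93
    assert rates["visual_before"] == 0.0


def test_rates_exclude_missing_calls():
    rows = [(1, "opposing", "oct", True, np.nan, np.nan),
            (2, "opposing", "oct", np.nan, np.nan, np.nan),
            (3, "opposing", "oct", False, np.nan, np.nan)]
    (summary,) = [r for r in detection_rates(_table(rows)) if r.group == "all"]
    assert (summary.n, summary.k_detected, summary.rate) == (2, 1, 0.5)


def test_rates_invariant_under_row_duplication():
    table = _calls_table({"oct": (7, 12)})
    doubled = pd.concat([table, table.assign(contact_id=table.contact_id + 100)])
    r1 = {(r.method, r.group): r.rate for r in detection_rates(table)}
    r2 = {(r.method, r.group): r.rate for r in detection_rates(doubled)}
    assert r1 == r2


def test_round_half_up_at_ties():
    assert round_half_up(0.625, 2) == 0.63
    assert round_half_up(6.25, 1) == 6.3
    assert round_half_up(4.375, 1) == 4.4


# ----------------------------------------------------------------- fisher

def _fisher_enumeration(k1, n1, k2, n2):
    """Independent oracle: sum of probabilities of all 2x2 tables with the
    observed margins whose probability does not exceed the observed one."""
    K = k1 + k2

    def prob(a):
        return math.comb(n1, a) * math.comb(n2, K - a)

    support = range(max(0, K - n2), min(n1, K) + 1)
    total = sum(prob(a) for a in support)
    p_obs = prob(k1)
    return sum(prob(a) for a in support if prob(a) <= p_obs * (1 + 1e-12)) / total


def test_fisher_identical_tables_give_p_one():
    assert fisher_exact(5, 10, 5, 10) == 1.0


def test_fisher_headline_comparison_significant():
    assert fisher_exact(11, 29, 27, 29) < 0.05


def test_fisher_symmetry():
    for k1, n1, k2, n2 in [(3, 9, 7, 11), (0, 5, 5, 5), (2, 12, 2, 7)]:
        assert fisher_exact(k1, n1, k2, n2) == pytest.approx(
            fisher_exact(k2, n2, k1, n1))


def test_fisher_matches_enumeration_small_margins():
    for n1 in range(1, 9):
        for n2 in range(1, 9):
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    assert fisher_exact(k1, n1, k2, n2) == pytest.approx(
                        _fisher_enumeration(k1, n1, k2, n2), abs=1e-10)


def test_fisher_rejects_bad_counts():
    with pytest.raises(ValueError):
        fisher_exact(5, 3, 1, 2)
    with pytest.raises(ValueError):
        fisher_exact(-1, 3, 1, 2)


# --------------------------------------------------------------- rm_anova

def test_identical_method_columns_give_p_one(rng):
    y = np.tile(rng.normal(size=(10, 1)), (1, 4))
    res = rm_anova(y)
    assert res.f_stat == 0.0 and res.p_value == 1.0
    assert set(res.letters.values()) == {"a"}


def test_two_methods_equal_paired_t_squared(rng):
    from scipy import stats as sps
    y = rng.normal(size=(14, 2)) + [0.0, 0.3]
    res = rm_anova(y)
    t, p = sps.ttest_rel(y[:, 0], y[:, 1])
    assert abs(res.f_stat - t**2) < 1e-9
    assert abs(res.p_value - p) < 1e-9


def test_matches_statsmodels_anovarm(rng):
    from statsmodels.stats.anova import AnovaRM
    y = rng.normal(size=(12, 3)) + [0.0, 0.25, 0.6]
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 3),
        "method": list("abc") * 12,
        "y": y.ravel(),
    })
    ref = AnovaRM(long, "y", "subject", within=["method"]).fit()
    res = rm_anova(y)
    assert res.f_stat == pytest.approx(float(ref.anova_table["F Value"].iloc[0]))
    assert res.p_value == pytest.approx(float(ref.anova_table["Pr > F"].iloc[0]))


def test_rm_anova_requires_complete_cases(rng):
    y = rng.normal(size=(5, 3))
    y[0, 1] = np.nan
    with pytest.raises(ValueError, match="complete"):
        rm_anova(y)
    with pytest.raises(ValueError, match="3 complete"):
        rm_anova(rng.normal(size=(2, 3)))


def test_bonferroni_correction_available(rng):
    y = rng.normal(size=(10, 3)) + [0.0, 1.0, 2.0]
    res = rm_anova(y, correction="bonferroni")
    assert res.correction == "bonferroni"
    assert (res.pairwise_p.to_numpy()[np.triu_indices(3, 1)] <= 1.0).all()


def test_fast_path_significance_matches_p_values(rng):
    y = rng.normal(0, 0.05, size=(20, 4)) + [0.0, 0.02, 0.2, 0.4]
    slow = rm_anova(y, compute_p=True)
    fast = rm_anova(y, compute_p=False)
    pd.testing.assert_frame_equal(slow.significant, fast.significant)
    assert slow.letters == fast.letters


# ---------------------------------------------------------------- letters

def test_all_similar_share_one_letter():
    p = np.ones((4, 4))
    assert letter_groups(p) == ["a", "a", "a", "a"]


def test_all_different_get_distinct_letters():
    p = np.zeros((3, 3))
    np.fill_diagonal(p, 1.0)
    assert letter_groups(p) == ["a", "b", "c"]


def test_chain_pattern_gets_bridging_letter():
    p = np.array([[1.0, 0.5, 0.01],
                  [0.5, 1.0, 0.5],
                  [0.01, 0.5, 1.0]])
    assert letter_groups(p) == ["a", "ab", "b"]


def test_letters_match_exhaustive_three_method_enumeration():
    """For every 3-method significance pattern, two methods share a letter
    iff their pair is non-significant (checked against brute force over all
    letter assignments)."""
    for bits in itertools.product([0, 1], repeat=3):
        sig = {(0, 1): bits[0], (0, 2): bits[1], (1, 2): bits[2]}
        p = np.ones((3, 3))
        for (i, j), s in sig.items():
            p[i, j] = p[j, i] = 0.01 if s else 0.5
        letters = letter_groups(p)
        for i, j in sig:
            share = bool(set(letters[i]) & set(letters[j]))
            assert share != bool(sig[(i, j)]), (bits, letters)


def test_letter_groups_validates_input():
    with pytest.raises(ValueError, match="square"):
        letter_groups(np.ones((2, 3)))
    with pytest.raises(ValueError, match="symmetric"):
        letter_groups(np.array([[1.0, 0.2], [0.8, 1.0]]))


# ----------------------------------------------- complete cases / mixedlm

def _measure_table(y, methods, missing=()):
    rows = []
    for s, row in enumerate(y):
        for m, value in zip(methods, row):
            v = np.nan if (s, m) in missing else value
            rows.append((s + 1, "opposing", m, not np.isnan(v), v, np.nan))
    return _table(rows)


def test_complete_case_filter_matches_injected_missingness(rng):
    methods = ["radiograph", "swir_r", "swir_ot", "swir_pt"]
    y = rng.normal(0.2, 0.05, size=(29, 4))
    missing = {(0, "swir_r"), (3, "radiograph"), (17, "swir_pt")}
    table = _measure_table(y, methods, missing)
    wide = complete_cases(table, "contrast", methods)
    assert len(wide) == 26
    res = compare_measure(table, "contrast", methods)
    assert res.n == 26


def test_mixed_effects_cross_check_agrees_on_clear_effect(rng):
    """Random-intercept model finds the same obvious separation as RM-ANOVA."""
    methods = ["radiograph", "swir_r"]
    y = rng.normal(0, 0.02, size=(20, 2)) + [0.13, 0.27]
    y += rng.normal(0, 0.03, size=(20, 1))
    table = _measure_table(y, methods)
    res = compare_measure(table, "contrast", methods)
    mixed = mixed_effects_pairwise(table, "contrast", methods)
    assert res.pairwise_p.loc["radiograph", "swir_r"] < 0.05
    assert mixed[("radiograph", "swir_r")] < 0.05
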