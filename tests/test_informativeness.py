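"""Threshold-sweep ROC/AUC against the exhaustive pair-counting oracle,
exact rank-sum p-values against complete enumeration, fold changes, and
whole-matrix scoring with planted ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seroclass import (
    auc_distribution,
    auc_pvalue,
    clone_auc,
    fold_change,
    rank_auc,
    score_all_clones,
)


def pair_counting_auc(wt, nb):
    """Oracle: P(WT > NB) + 1/2 P(WT = NB) by exhaustive pair loops."""
    wins = sum((w > n) + 0.5 * (w == n) for w in wt for n in nb)
    return wins / (len(wt) * len(nb))


def test_perfect_separation_and_symmetry():
    assert clone_auc([200, 210], [10, 20]) == 1.0
    assert clone_auc([10, 20], [200, 210]) == 0.0
    assert clone_auc([5, 7, 9], [5, 7, 9]) == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(20))
def test_threshold_sweep_equals_pair_counting_on_random_integers(seed):
    rng = np.random.default_rng(seed)
    wt = rng.integers(0, 256, rng.integers(2, 30))
    nb = rng.integers(0, 256, rng.integers(2, 30))
    oracle = pair_counting_auc(wt.tolist(), nb.tolist())
    assert clone_auc(wt, nb) == pytest.approx(oracle, abs=1e-12)
    assert rank_auc(wt, nb) == pytest.approx(oracle, abs=1e-12)


@given(
    wt=st.lists(st.integers(0, 255), min_size=1, max_size=12),
    nb=st.lists(st.integers(0, 255), min_size=1, max_size=12),
)
@settings(max_examples=200, deadline=None)
def test_antisymmetry_property(wt, nb):
    assert clone_auc(wt, nb) == pytest.approx(1.0 - clone_auc(nb, wt), abs=1e-12)


@given(
    wt=st.lists(st.integers(0, 100), min_size=2, max_size=10),
    nb=st.lists(st.integers(0, 100), min_size=2, max_size=10),
)
@settings(max_examples=100, deadline=None)
def test_invariance_under_monotone_transform(wt, nb):
    wt, nb = np.array(wt, dtype=float), np.array(nb, dtype=float)
    base = clone_auc(wt, nb)
    assert clone_auc(np.exp(wt / 20), np.exp(nb / 20)) == pytest.approx(base, abs=1e-9)


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        clone_auc([], [1, 2])
    with pytest.raises(ValueError):
        auc_pvalue([1, 2], [])


def test_exact_pvalue_for_complete_3v3_separation():
    # 2 of the C(6,3)=20 assignments are as extreme -> two-sided p = 0.1
    assert auc_pvalue([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)


def test_identical_groups_give_p_near_one():
    assert auc_pvalue([5, 5, 6, 7], [5, 5, 6, 7]) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_exact_enumeration_matches_scipy_on_tie_free_data(seed):
    from scipy import stats

    rng = np.random.default_rng(seed)
    values = rng.permutation(100)[:12].astype(float)  # distinct => no ties
    wt, nb = values[:6], values[6:]
    expected = stats.mannwhitneyu(wt, nb, alternative="two-sided", method="exact").pvalue
    assert auc_pvalue(wt, nb) == pytest.approx(expected, abs=1e-12)


def test_large_planted_shift_is_significant():
    rng = np.random.default_rng(0)
    nb = rng.normal(150, 10, 20)
    wt = rng.normal(60, 10, 25)
    assert auc_pvalue(wt, nb) < 0.01


@pytest.mark.parametrize(
    "nb,wt,expected",
    [([90, 90], [40, 40], 2.25), ([7, 7], [7, 7], 1.0), ([0, 0], [5, 5], 0.0)],
)
def test_fold_change_is_ratio_of_group_means(nb, wt, expected):
    assert fold_change(nb, wt) == pytest.approx(expected)


def test_fold_change_undefined_for_zero_denominator():
    assert np.isnan(fold_change([5, 5], [0, 0]))


def test_score_all_clones_recovers_planted_truth(small_cohort, small_normalized):
    scoring = score_all_clones(small_normalized)
    scores = scoring.scores
    planted = small_cohort.truth.index.intersection(scores.index)
    assert len(planted) == len(small_cohort.truth)  # planted clones survive filtering
    assert scores.loc[planted, "informative"].all()
    assert (scores.loc[planted, "direction"] == "NB-reactive").all()
    assert (scores.loc[planted, "auc"] < 0.3).all()
    assert (scores.loc[planted, "fold_change"] > 1).all()


def test_informativeness_call_is_consistent_with_auc(small_normalized):
    scores = score_all_clones(small_normalized).scores
    expected = (scores["auc"] < 0.3) | (scores["auc"] > 0.7)
    assert (scores["informative"] == expected).all()
    assert (scores.loc[scores["auc"] > 0.7, "direction"] == "WT-reactive").all()
    assert (scores.loc[scores["auc"] < 0.3, "direction"] == "NB-reactive").all()
    assert (scores.loc[~scores["informative"], "direction"] == "none").all()
    # BH never shrinks a raw p-value
    assert (scores["q_value"] >= scores["p_value"] - 1e-12).all()


def test_auc_distribution_partitions_all_clones(small_normalized):
    scoring = score_all_clones(small_normalized)
    dist = scoring.auc_distribution
    assert dist["all_clones"].sum() == len(scoring.scores)
    assert dist["in_frame"].sum() == int(scoring.scores["in_frame"].sum())
    assert (dist["in_frame"] <= dist["all_clones"]).all()
    assert dist["bin"].iloc[0] == "0.9-1.0" and dist["bin"].iloc[-1] == "0.0-0.1"


def test_auc_of_exactly_one_lands_in_top_bin():
    import pandas as pd

    scores = pd.DataFrame({"auc": [1.0, 0.0], "in_frame": [True, False]})
    dist = auc_distribution(scores)
    assert dist.loc[dist["bin"] == "0.9-1.0", "all_clones"].iloc[0] == 1
    assert dist.loc[dist["bin"] == "0.0-0.1", "all_clones"].iloc[0] == 1


def test_group_absent_is_an_error(small_normalized):
    with pytest.raises(ValueError, match="absent"):
        score_all_clones(small_normalized, group_a="NB", group_b="XX")
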