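"""Per-clone ROC/AUC informativeness ranking.

For each clone the two serum groups are compared with a threshold-sweep
ROC curve.  The convention: Wilms tumor (group B) sera with intensity >=
threshold are true positives, neuroblastoma (group A) sera with intensity
>= threshold are false positives.  The area under the resulting
(1 - specificity, sensitivity) curve — by trapezoidal integration over
all distinct pooled intensity values — equals the probability that a
random WT intensity exceeds a random NB intensity, with ties counted 1/2.

AUC < 0.3 therefore flags clones more reactive in neuroblastoma sera and
AUC > 0.7 clones more reactive in Wilms tumor sera; both are called
"informative".  Mann-Whitney rank-sum p-values (exact by enumeration for
small groups) and NB/WT fold changes accompany each AUC, plus
Benjamini-Hochberg q-values across clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileMatrix, _require_stage

AUC_LOW = 0.3
AUC_HIGH = 0.7

#: Table layout of the AUC decile distribution, highest bin first.
AUC_BIN_LABELS = [f"{lo / 10:.1f}-{(lo + 1) / 10:.1f}" for lo in range(9, -1, -1)]


def clone_auc(wt_values, nb_values) -> float:
    """Threshold-sweep ROC AUC for one clone (positive class = WT).

    Sweeps the decision threshold over every distinct pooled intensity
    (plus a sentinel above the maximum); at threshold ``h`` a WT serum
    with value >= h counts as TP, an NB serum with value >= h as FP.  The
    trapezoidal area under (FPR, TPR) is returned.
    """
    wt = np.asarray(wt_values, dtype=float)
    nb = np.asarray(nb_values, dtype=float)
    if wt.size == 0 or nb.size == 0:
        raise ValueError("both groups need at least one intensity value")
    thresholds = np.unique(np.concatenate([wt, nb]))
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)  # (0, 0) endpoint
    # at h = min(pooled) every serum is >= h, giving the (1, 1) endpoint
    tpr = (wt[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (nb[None, :] >= thresholds[:, None]).mean(axis=1)
    return float(-np.trapezoid(tpr, fpr))  # h ascending => fpr descending


def rank_auc(wt_values, nb_values) -> float:
    """Pair-counting AUC: P(WT > NB) + 1/2 P(WT = NB), via rank sums.

    Used as the independent cross-check of :func:`clone_auc`; the two are
    mathematically identical.
    """
    wt = np.asarray(wt_values, dtype=float)
    nb = np.asarray(nb_values, dtype=float)
    ranks = stats.rankdata(np.concatenate([wt, nb]))
    u = ranks[: wt.size].sum() - wt.size * (wt.size + 1) / 2
    return float(u / (wt.size * nb.size))


def auc_pvalue(wt_values, nb_values, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney p-value for a clone's group difference.

    For groups of at most ``exact_max_n`` sera each, the null
    distribution of the U statistic is enumerated over all label
    assignments (handling ties exactly); otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    wt = np.asarray(wt_values, dtype=float)
    nb = np.asarray(nb_values, dtype=float)
    if wt.size == 0 or nb.size == 0:
        raise ValueError("both groups need at least one intensity value")
    if wt.size <= exact_max_n and nb.size <= exact_max_n:
        return _exact_mannwhitney_pvalue(wt, nb)
    res = stats.mannwhitneyu(wt, nb, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_mannwhitney_pvalue(wt: np.ndarray, nb: np.ndarray) -> float:
    """Exact two-sided p by complete enumeration of group assignments."""
    pooled = np.concatenate([wt, nb])
    ranks = stats.rankdata(pooled)
    n_wt, n = wt.size, pooled.size
    mu = n_wt * nb.size / 2.0
    offset = n_wt * (n_wt + 1) / 2.0
    u_obs = ranks[:n_wt].sum() - offset
    dev = abs(u_obs - mu) - 1e-9
    hits = sum(
        1
        for idx in combinations(range(n), n_wt)
        if abs(ranks[list(idx)].sum() - offset - mu) >= dev
    )
    return hits / comb(n, n_wt)


def fold_change(nb_values, wt_values) -> float:
    """Ratio of group mean intensities, NB over WT (NaN if WT mean is 0)."""
    nb_mean = float(np.mean(nb_values))
    wt_mean = float(np.mean(wt_values))
    if wt_mean == 0:
        return float("nan")
    return nb_mean / wt_mean


def _direction(auc: float, label_a: str, label_b: str) -> str:
    if auc > AUC_HIGH:
        return f"{label_b}-reactive"
    if auc < AUC_LOW:
        return f"{label_a}-reactive"
    return "none"


@dataclass(frozen=True)
class CloneScoring:
    """Per-clone scores plus the decile distribution of AUC values."""

    scores: pd.DataFrame        # clone_id index; auc, p_value, q_value, ...
    auc_distribution: pd.DataFrame  # bin, all_clones, in_frame


def score_all_clones(
    m: ProfileMatrix,
    group_a: str = "NB",
    group_b: str = "WT",
) -> CloneScoring:
    """Score every clone of a normalized matrix.

    Group B (Wilms tumor by default) is the ROC-positive class, so
    AUC > 0.7 means B-reactive and AUC < 0.3 means A-reactive.
    """
    _require_stage(m, "normalized", "score_all_clones")
    groups = m.groups()
    for g in (group_a, group_b):
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} absent from serum annotation")
    a_cols = m.values.columns[(groups == group_a).to_numpy()]
    b_cols = m.values.columns[(groups == group_b).to_numpy()]
    a_block = m.values[a_cols].to_numpy(dtype=float)
    b_block = m.values[b_cols].to_numpy(dtype=float)

    records = []
    for i, clone_id in enumerate(m.values.index):
        nb, wt = a_block[i], b_block[i]
        auc = clone_auc(wt, nb)
        records.append(
            {
                "clone_id": clone_id,
                "auc": auc,
                "p_value": auc_pvalue(wt, nb),
                "fold_change": fold_change(nb, wt),
                "informative": auc < AUC_LOW or auc > AUC_HIGH,
                "direction": _direction(auc, group_a, group_b),
            }
        )
    scores = pd.DataFrame.from_records(records).set_index("clone_id")
    scores["q_value"] = multipletests(scores["p_value"].to_numpy(), method="fdr_bh")[1]
    scores["in_frame"] = m.clones.loc[scores.index, "in_frame"].astype(bool)
    scores["antigen_name"] = m.clones.loc[scores.index, "antigen_name"]
    return CloneScoring(scores=scores, auc_distribution=auc_distribution(scores))


def auc_distribution(scores: pd.DataFrame) -> pd.DataFrame:
    """Decile histogram of AUC values, bins [0,0.1) ... [0.9,1.0].

    The top bin is closed so an AUC of exactly 1 is counted.  Rows follow
    the customary top-down table order (0.9-1.0 first).
    """
    bins = np.minimum((scores["auc"].to_numpy() * 10).astype(int), 9)
    all_counts = np.bincount(bins, minlength=10)[::-1]
    inframe = np.bincount(
        bins[scores["in_frame"].to_numpy(dtype=bool)], minlength=10
    )[::-1]
    return pd.DataFrame(
        {"bin": AUC_BIN_LABELS, "all_clones": all_counts, "in_frame": inframe}
    )
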