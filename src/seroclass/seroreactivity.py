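"""Binarized seroreactivity calls and group-wise reactivity frequencies.

A clone is "reactive" with a serum when its normalized intensity strictly
exceeds a threshold (default 50 on the 0-255 scale).  From the binary
clone x serum matrix the module derives per-group reactivity frequencies,
their decile histogram (for all clones and for in-frame clones), and the
overlap of highly reactive in-frame clones between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix, _require_stage

REACTIVITY_THRESHOLD = 50.0

#: Decile bin labels; bin k covers ((k-1)/10, k/10] with 0 in the first bin.
BIN_LABELS = [
    "0.00-10.00", "10.01-20.00", "20.01-30.00", "30.01-40.00", "40.01-50.00",
    "50.01-60.00", "60.01-70.00", "70.01-80.00", "80.01-90.00", "90.01-100.00",
]


def binarize(m: ProfileMatrix, threshold: float = REACTIVITY_THRESHOLD) -> pd.DataFrame:
    """Binary reactivity calls: strictly above ``threshold`` is reactive."""
    _require_stage(m, "normalized", "binarize")
    return m.values > threshold


@dataclass(frozen=True)
class ReactivityTable:
    """Per-clone reactive-serum counts and frequencies for two groups.

    ``counts`` holds integer columns ``reactive_<g>`` and ``n_<g>`` per
    group label ``g`` so frequencies can be binned in exact integer
    arithmetic; ``frequencies`` holds the corresponding fractions.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    in_frame: pd.Series
    group_labels: tuple[str, str]


def reactivity_frequencies(binary: pd.DataFrame, m: ProfileMatrix) -> ReactivityTable:
    """Fraction of reactive sera per clone and group."""
    groups = m.groups()
    labels = tuple(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two serum groups, got {list(labels)}")
    counts = {}
    freqs = {}
    for g in labels:
        cols = binary.columns[(groups == g).to_numpy()]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no sera")
        counts[f"reactive_{g}"] = binary[cols].sum(axis=1).astype(int)
        counts[f"n_{g}"] = len(cols)
        freqs[g] = counts[f"reactive_{g}"] / len(cols)
    in_frame = m.clones.loc[binary.index, "in_frame"].astype(bool)
    return ReactivityTable(
        counts=pd.DataFrame(counts),
        frequencies=pd.DataFrame(freqs),
        in_frame=in_frame,
        group_labels=labels,
    )


def _decile_bin(reactive: np.ndarray, n: int) -> np.ndarray:
    """Bin index 0..9 for frequency reactive/n, computed in integers.

    Bin k (0-based) covers (k/10, (k+1)/10], except bin 0 which also
    contains 0 — i.e. the smallest k with reactive*10 <= (k+1)*n.
    """
    k = -(-10 * reactive // n) - 1  # ceil(10 r / n) - 1
    return np.clip(k, 0, 9).astype(int)


def frequency_histogram(rt: ReactivityTable, group: str) -> pd.DataFrame:
    """Decile histogram of reactivity frequencies for one group.

    Returns a 10-row frame (``bin``, ``all_clones``, ``in_frame``): the
    number of clones, and of in-frame clones, whose reactive fraction
    falls in each decile interval.
    """
    reactive = rt.counts[f"reactive_{group}"].to_numpy()
    n = int(rt.counts[f"n_{group}"].iloc[0])
    bins = _decile_bin(reactive, n)
    all_counts = np.bincount(bins, minlength=10)
    inframe_counts = np.bincount(bins[rt.in_frame.to_numpy()], minlength=10)
    return pd.DataFrame(
        {"bin": BIN_LABELS, "all_clones": all_counts, "in_frame": inframe_counts}
    )


def high_reactivity_overlap(rt: ReactivityTable, cutoff: float = 0.9) -> pd.DataFrame:
    """In-frame clones reactive in strictly more than ``cutoff`` of sera.

    Lists, per clone, which group(s) exceed the cutoff and the frequency
    in both groups, so shared highly reactive antigens are visible.
    Rows are sorted by clone ID; membership is order-invariant.
    """
    a, b = rt.group_labels
    freq = rt.frequencies.loc[rt.in_frame]
    high_a = freq[a] > cutoff
    high_b = freq[b] > cutoff
    sel = freq.loc[high_a | high_b].sort_index()
    return pd.DataFrame(
        {
            f"frequency_{a}": sel[a],
            f"frequency_{b}": sel[b],
            f"high_{a}": high_a.loc[sel.index],
            f"high_{b}": high_b.loc[sel.index],
            "both": (high_a & high_b).loc[sel.index],
        }
    )
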