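"""Quantile normalization across arrays.

Forces every serum column onto the common reference distribution — the
across-array mean of order statistics — so that array-to-array scale and
offset effects vanish while within-array rank order is preserved.  Ties
(abundant on an integer 0-255 scale) receive the average of their tied
positions' reference values, which makes the transform idempotent.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .profiles import ProfileError, ProfileMatrix, _require_stage


def quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a 2-D array (rows = features).

    Each column is mapped to the mean of column-wise order statistics;
    tied entries within a column get the mean reference value of their
    tied rank positions.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.isnan(x).any():
        raise ValueError("matrix contains NAs; impute before normalizing")
    reference = np.sort(x, axis=0).mean(axis=1)
    cum = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        # value uniq[g] occupies sorted positions ends[g-1] .. ends[g]-1;
        # its tied entries all receive the mean reference over that span
        ends = np.cumsum(counts)
        starts = ends - counts
        group_means = (cum[ends] - cum[starts]) / counts
        out[:, j] = group_means[inv]
    return out


def quantile_normalize(m: ProfileMatrix) -> ProfileMatrix:
    """Quantile-normalize a filtered, fully imputed profile matrix."""
    _require_stage(m, "filtered", "quantile_normalize")
    if m.values.isna().to_numpy().any():
        raise ProfileError("matrix contains NAs; run impute_missing first")
    normalized = m.values.copy()
    normalized.iloc[:, :] = quantile_normalize_values(m.values.to_numpy(dtype=float))
    return replace(m, values=normalized, stage="normalized")
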