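"""Clone-by-serum intensity profiles: data model, TSV IO, replicate
averaging, NA-based clone exclusion and missing-value imputation.

The central container is :class:`ProfileMatrix`, a clones x sera matrix of
spot intensities together with the clone and serum annotation tables.  A
matrix moves monotonically through the stages

    ``raw_duplicates`` -> ``averaged`` -> ``filtered`` -> ``normalized``

mirroring the analysis order: duplicate spots are averaged per clone,
clones with too many not-available (NA) values are excluded, remaining NAs
are imputed, and finally arrays are quantile-normalized (see
:mod:`seroclass.normalization`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("raw_duplicates", "averaged", "filtered", "normalized")

#: Raw spot intensities live on an 8-bit scanner scale.
INTENSITY_MIN = 0
INTENSITY_MAX = 255


class ProfileError(ValueError):
    """Raised for malformed profile matrices or annotation tables."""


@dataclass(frozen=True)
class ProfileMatrix:
    """Clones x sera intensity matrix with annotations.

    Parameters
    ----------
    values
        DataFrame with clone IDs as index and serum IDs as columns.  At
        stage ``raw_duplicates`` every clone ID appears exactly twice (one
        row per duplicate spot); at later stages exactly once.  NA cells
        are ``NaN``.
    clones
        Clone annotation table indexed by clone ID with columns
        ``in_frame`` (bool) and ``antigen_name`` (str, may be empty).
    sera
        Serum annotation table indexed by serum ID with columns ``group``
        (e.g. ``NB``/``WT``) and ``treatment``.
    stage
        One of :data:`STAGES`.
    """

    values: pd.DataFrame
    clones: pd.DataFrame
    sera: pd.DataFrame
    stage: str = "raw_duplicates"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ProfileError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.sera.index.has_duplicates:
            dupes = self.sera.index[self.sera.index.duplicated()].unique().tolist()
            raise ProfileError(f"duplicated serum IDs: {dupes}")
        if self.clones.index.has_duplicates:
            dupes = self.clones.index[self.clones.index.duplicated()].unique().tolist()
            raise ProfileError(f"duplicated clone IDs in annotation: {dupes}")
        if list(self.values.columns) != list(self.sera.index):
            missing = set(self.values.columns) ^ set(self.sera.index)
            raise ProfileError(
                f"matrix columns and serum annotation disagree (mismatch: {sorted(missing)})"
            )
        unknown = set(self.values.index) - set(self.clones.index)
        if unknown:
            raise ProfileError(f"matrix rows not in clone annotation: {sorted(unknown)[:5]}")
        counts = self.values.index.value_counts()
        if self.stage == "raw_duplicates":
            bad = counts[counts != 2]
            if len(bad):
                raise ProfileError(
                    f"raw_duplicates requires exactly two rows per clone; offending: "
                    f"{bad.index.tolist()[:5]}"
                )
        else:
            bad = counts[counts != 1]
            if len(bad):
                raise ProfileError(
                    f"stage {self.stage} requires one row per clone; offending: "
                    f"{bad.index.tolist()[:5]}"
                )
        if self.stage != "normalized":
            v = self.values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.nanmin(v, initial=INTENSITY_MIN) < INTENSITY_MIN or np.nanmax(
                    v, initial=INTENSITY_MAX
                ) > INTENSITY_MAX:
                    raise ProfileError(
                        f"raw intensities must lie in [{INTENSITY_MIN}, {INTENSITY_MAX}]"
                    )

    @property
    def na_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_clones(self) -> int:
        return self.values.index.nunique()

    @property
    def n_sera(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Group label per serum, aligned to matrix columns."""
        return self.sera.loc[self.values.columns, "group"]

    def in_frame_ids(self) -> pd.Index:
        """Clone IDs flagged as in-frame, restricted to the current matrix."""
        inframe = self.clones.index[self.clones["in_frame"].astype(bool)]
        return self.values.index.unique().intersection(inframe)


def _require_stage(m: ProfileMatrix, stage: str, op: str) -> None:
    if m.stage != stage:
        raise ProfileError(f"{op} requires stage {stage!r}, got {m.stage!r}")


def average_replicates(m: ProfileMatrix) -> ProfileMatrix:
    """Average duplicate spots into one row per clone.

    A cell is the mean of its available duplicates; it stays NA only when
    both duplicates are NA.  Row order follows first appearance.
    """
    _require_stage(m, "raw_duplicates", "average_replicates")
    order = m.values.index.unique()
    averaged = m.values.groupby(level=0, sort=False).mean().loc[order]
    return replace(m, values=averaged, stage="averaged")


def filter_na_clones(m: ProfileMatrix, max_na: int = 10) -> tuple[ProfileMatrix, list[str]]:
    """Drop clones with strictly more than ``max_na`` NA values.

    The exclusion rule is strict: a clone with exactly ``max_na`` NAs is
    retained.  Returns the filtered matrix and the list of excluded clone
    IDs (the removal log).
    """
    _require_stage(m, "averaged", "filter_na_clones")
    na_counts = m.values.isna().sum(axis=1)
    excluded = na_counts.index[na_counts > max_na].tolist()
    kept = m.values.loc[na_counts <= max_na]
    return replace(m, values=kept, stage="filtered"), excluded


def impute_missing(m: ProfileMatrix) -> tuple[ProfileMatrix, int]:
    """Fill remaining NA cells with the clone's mean over sera sharing the
    cell's treatment status.

    Clones surviving the NA filter carry at most ``max_na`` missing cells;
    mean imputation within the treatment cohort keeps per-clone frequency
    statistics unbiased.  Falls back to the clone's overall mean when an
    entire treatment cohort is missing, then to the global matrix mean.
    Returns the imputed matrix and the number of imputed cells.
    """
    _require_stage(m, "filtered", "impute_missing")
    values = m.values.copy()
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing == 0:
        return m, 0
    treatment = m.sera.loc[values.columns, "treatment"]
    for level in treatment.unique():
        cols = values.columns[(treatment == level).to_numpy()]
        block = values[cols]
        values[cols] = block.apply(lambda row: row.fillna(row.mean()), axis=1)
    # cohorts that were entirely NA for a clone: fall back across cohorts
    if values.isna().to_numpy().any():
        values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
        values = values.fillna(float(np.nanmean(values.to_numpy(dtype=float))))
    return replace(m, values=values), n_missing


# ---------------------------------------------------------------------------
# TSV input/output
# ---------------------------------------------------------------------------

_NA_SENTINELS = ("", "NA", "na", "NaN", "nan")


def _parse_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Convert a string-valued frame to float, accepting decimal commas."""
    def conv(x: object) -> float:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return np.nan
        s = str(x).strip()
        if s in _NA_SENTINELS:
            return np.nan
        s = s.replace(",", ".")
        try:
            return float(s)
        except ValueError as exc:
            raise ProfileError(f"non-numeric cell {x!r} in {what}") from exc

    return df.map(conv)


def read_profiles(
    matrix_path: str | Path,
    clone_annot_path: str | Path,
    serum_annot_path: str | Path,
) -> ProfileMatrix:
    """Read a profile matrix and its annotation tables from TSV.

    The matrix file has clone IDs in the first column and one column per
    serum; empty cells and ``NA`` are parsed as missing.  Decimal commas
    are accepted and normalized to points.  The stage is taken from a
    ``<matrix>.meta.json`` sidecar when present, else inferred from the
    row multiplicity (two rows per clone -> ``raw_duplicates``, one ->
    ``averaged``).
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = _parse_numeric(raw, f"matrix {matrix_path.name}")
    values.index.name = "clone_id"

    clones = pd.read_csv(clone_annot_path, sep="\t", index_col=0, dtype=str)
    clones["in_frame"] = clones["in_frame"].map(
        lambda s: str(s).strip().lower() in ("1", "true", "yes")
    )
    clones["antigen_name"] = clones.get("antigen_name", "").fillna("")

    sera = pd.read_csv(serum_annot_path, sep="\t", index_col=0, dtype=str)
    if sera.index.has_duplicates:
        dupes = sera.index[sera.index.duplicated()].unique().tolist()
        raise ProfileError(f"duplicated serum IDs in {serum_annot_path}: {dupes}")

    meta = matrix_path.with_suffix(matrix_path.suffix + ".meta.json")
    if meta.exists():
        stage = json.loads(meta.read_text())["stage"]
    else:
        counts = values.index.value_counts()
        stage = "raw_duplicates" if (counts == 2).all() else "averaged"
    return ProfileMatrix(values=values, clones=clones, sera=sera, stage=stage)


def write_profiles(m: ProfileMatrix, out_path: str | Path) -> Path:
    """Write the matrix to TSV (NA cells as empty fields) plus a
    ``.meta.json`` sidecar recording the stage."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(out_path, sep="\t", na_rep="")
    meta = out_path.with_suffix(out_path.suffix + ".meta.json")
    meta.write_text(json.dumps({"stage": m.stage}) + "\n")
    return out_path


def write_annotations(m: ProfileMatrix, clone_path: str | Path, serum_path: str | Path) -> None:
    """Write the clone and serum annotation tables to TSV."""
    clones = m.clones.copy()
    clones["in_frame"] = clones["in_frame"].astype(bool).map({True: "true", False: "false"})
    clones.to_csv(clone_path, sep="\t", index_label="clone_id")
    m.sera.to_csv(serum_path, sep="\t", index_label="serum_id")
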