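"""Replicate averaging, the strict >max_na exclusion rule, imputation,
and TSV round-trips (including decimal-comma input)."""

import numpy as np
import pandas as pd
import pytest

from seroclass import (
    ProfileError,
    ProfileMatrix,
    average_replicates,
    filter_na_clones,
    impute_missing,
    read_profiles,
    write_annotations,
    write_profiles,
)

from conftest import make_matrix

NA = np.nan


def test_replicate_averaging_arithmetic():
    m = make_matrix(
        [[100, NA, NA], [120, 80, NA],   # clone C000: pairs (100,120), (NA,80), (NA,NA)
         [10, 20, 30], [10, 20, 30]],    # clone C001: identical duplicates
        stage="raw_duplicates",
    )
    out = average_replicates(m)
    assert out.stage == "averaged"
    assert out.values.shape == (2, 3)
    row = out.values.loc["C000"]
    assert row.iloc[0] == 110.0          # mean of both duplicates
    assert row.iloc[1] == 80.0           # single available duplicate
    assert np.isnan(row.iloc[2])         # both duplicates missing
    assert (out.values.loc["C001"] == [10, 20, 30]).all()


def test_averaging_preserves_input(small_cohort):
    before = small_cohort.profiles.values.copy()
    average_replicates(small_cohort.profiles)
    pd.testing.assert_frame_equal(small_cohort.profiles.values, before)


@pytest.mark.parametrize("n_na,kept", [(9, True), (10, True), (11, False)])
def test_na_filter_is_strictly_greater_than(n_na, kept):
    values = np.full((3, 12), 100.0)
    values[1, :n_na] = NA
    m = make_matrix(values)
    out, excluded = filter_na_clones(m, max_na=10)
    assert ("C001" in out.values.index) is kept
    assert ("C001" in excluded) is not kept
    assert out.stage == "filtered"


def test_na_filter_count_matches_brute_force():
    rng = np.random.default_rng(5)
    values = rng.integers(0, 256, (40, 15)).astype(float)
    mask = rng.random((40, 15)) < 0.3
    values[mask] = NA
    m = make_matrix(values)
    out, excluded = filter_na_clones(m, max_na=3)
    brute = sum(1 for i in range(40) if np.isnan(values[i]).sum() > 3)
    assert len(excluded) == brute
    assert out.values.shape[0] == 40 - brute


def test_imputation_uses_treatment_cohort_mean():
    values = np.array([[10.0, 20.0, NA, 7.0], [1.0, 2.0, 3.0, 4.0]])
    m = make_matrix(values, treatment=["untreated"] * 3 + ["treated"], stage="averaged")
    filtered, _ = filter_na_clones(m)
    out, n = impute_missing(filtered)
    assert n == 1
    assert out.values.loc["C000"].iloc[2] == 15.0  # mean of the untreated cells
    assert not out.values.isna().to_numpy().any()


def test_round_trip_preserves_values_nas_and_stage(tmp_path, small_cohort):
    m = small_cohort.profiles
    write_profiles(m, tmp_path / "matrix.tsv")
    write_annotations(m, tmp_path / "clones.tsv", tmp_path / "sera.tsv")
    back = read_profiles(tmp_path / "matrix.tsv", tmp_path / "clones.tsv", tmp_path / "sera.tsv")
    assert back.stage == m.stage
    pd.testing.assert_frame_equal(back.values, m.values)
    assert back.clones["in_frame"].equals(m.clones["in_frame"])


def test_decimal_commas_are_accepted(tmp_path):
    (tmp_path / "m.tsv").write_text("clone_id\tS0\tS1\nC000\t0,944\t12\nC001\t\t3,5\n")
    (tmp_path / "c.tsv").write_text("clone_id\tin_frame\tantigen_name\nC000\ttrue\t\nC001\tfalse\t\n")
    (tmp_path / "s.tsv").write_text("serum_id\tgroup\ttreatment\nS0\tNB\tuntreated\nS1\tWT\tuntreated\n")
    m = read_profiles(tmp_path / "m.tsv", tmp_path / "c.tsv", tmp_path / "s.tsv")
    assert m.values.loc["C000", "S0"] == pytest.approx(0.944)
    assert m.values.loc["C001", "S1"] == pytest.approx(3.5)
    assert np.isnan(m.values.loc["C001", "S0"])
    assert m.stage == "averaged"


def test_duplicated_serum_id_is_rejected(tmp_path):
    (tmp_path / "m.tsv").write_text("clone_id\tS0\tS0\nC000\t1\t2\n")
    (tmp_path / "c.tsv").write_text("clone_id\tin_frame\tantigen_name\nC000\ttrue\t\n")
    (tmp_path / "s.tsv").write_text(
        "serum_id\tgroup\ttreatment\nS0\tNB\tuntreated\nS0\tWT\tuntreated\n"
    )
    with pytest.raises(ProfileError, match="duplicated serum"):
        read_profiles(tmp_path / "m.tsv", tmp_path / "c.tsv", tmp_path / "s.tsv")


def test_non_numeric_cell_is_a_parse_error(tmp_path):
    (tmp_path / "m.tsv").write_text("clone_id\tS0\nC000\tbogus\n")
    (tmp_path / "c.tsv").write_text("clone_id\tin_frame\tantigen_name\nC000\ttrue\t\n")
    (tmp_path / "s.tsv").write_text("serum_id\tgroup\ttreatment\nS0\tNB\tuntreated\n")
    with pytest.raises(ProfileError, match="non-numeric"):
        read_profiles(tmp_path / "m.tsv", tmp_path / "c.tsv", tmp_path / "s.tsv")


def test_out_of_range_intensities_are_rejected():
    with pytest.raises(ProfileError, match="255"):
        make_matrix([[300.0, 10.0]])


def test_stage_transitions_are_enforced(small_cohort):
    with pytest.raises(ProfileError, match="stage"):
        filter_na_clones(small_cohort.profiles)  # still raw_duplicates
    with pytest.raises(ProfileError, match="stage"):
        average_replicates(average_replicates(small_cohort.profiles))
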