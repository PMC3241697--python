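import numpy as np
import pandas as pd
import pytest

from seroclass import ProfileMatrix, SyntheticConfig, prepare_matrix, simulate_cohort


def make_matrix(values, groups=None, in_frame=None, stage="averaged", treatment=None):
    """Build a ProfileMatrix from a 2-D array-like (rows = clones)."""
    values = np.asarray(values, dtype=float)
    n_clones = len(np.unique([f"C{i:03d}" for i in range(values.shape[0])]))
    if stage == "raw_duplicates":
        n_clones = values.shape[0] // 2
        index = pd.Index(np.repeat([f"C{i:03d}" for i in range(n_clones)], 2), name="clone_id")
    else:
        n_clones = values.shape[0]
        index = pd.Index([f"C{i:03d}" for i in range(n_clones)], name="clone_id")
    serum_ids = [f"S{j:03d}" for j in range(values.shape[1])]
    if groups is None:
        half = values.shape[1] // 2
        groups = ["NB"] * half + ["WT"] * (values.shape[1] - half)
    if in_frame is None:
        in_frame = [True] * n_clones
    if treatment is None:
        treatment = ["untreated"] * values.shape[1]
    clones = pd.DataFrame(
        {"in_frame": in_frame, "antigen_name": ""},
        index=pd.Index([f"C{i:03d}" for i in range(n_clones)], name="clone_id"),
    )
    sera = pd.DataFrame(
        {"group": groups, "treatment": treatment},
        index=pd.Index(serum_ids, name="serum_id"),
    )
    return ProfileMatrix(
        values=pd.DataFrame(values, index=index, columns=serum_ids),
        clones=clones,
        sera=sera,
        stage=stage,
    )


SMALL_CONFIG = SyntheticConfig(
    n_clones=80,
    n_inframe=30,
    n_sera_a=8,
    n_sera_b=10,
    n_informative=4,
    effect_shift=100.0,
    n_excluded_target=5,
    na_rate=0.02,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    norm, excluded, _ = prepare_matrix(small_cohort.profiles)
    return norm
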