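"""Synthetic serum-profile cohorts with macroarray-like structure.

The generator emulates a protein macroarray experiment: each clone is
spotted in duplicate on every array, spot intensities are 8-bit integers
(0-255), some spot pairs are unreadable (NA), and two serum groups are
compared.  The statistical structure targeted is:

* per-clone reactivity prevalence (fraction of sera whose normalized
  intensity exceeds the seroreactivity threshold of 50) is unimodal
  around ~50%, so the binarized frequency histogram has the hump shape
  observed on real arrays;
* a small set of planted informative clones carries a mean intensity
  shift in one group, so downstream ROC/AUC ranking and classification
  have a known ground truth;
* a configurable number of clones carries enough NA values to trip the
  ">10 NAs" exclusion filter.

The latent model: clone ``c`` has baseline ``b_c = 50 + sigma_serum *
Phi^-1(p_c)`` with prevalence ``p_c ~ Beta(k*m, k*(1-m))``, so that the
probability of a serum's latent intensity exceeding 50 is exactly
``p_c``.  A serum's latent intensity adds Gaussian serum-level noise and
an array-wide additive offset (the array-to-array variation that quantile
normalization removes); duplicate spots are two Gaussian draws around the
latent value, rounded and clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import INTENSITY_MAX, INTENSITY_MIN, ProfileMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a simulated serum cohort.

    Defaults reproduce the array geometry and cohort sizes of the
    untreated-group comparison: 1,827 clones (509 in-frame) in duplicate,
    30 neuroblastoma (group A) versus 53 Wilms tumor (group B) sera,
    16 planted markers more reactive in group A, and 308 clones designed
    to fail the NA-exclusion rule.
    """

    n_clones: int = 1827
    n_inframe: int = 509
    n_sera_a: int = 30
    n_sera_b: int = 53
    n_informative: int = 16
    effect_shift: float = 80.0          # intensity offset added in group A
    reactive_fraction_mean: float = 0.5  # mean per-clone reactivity prevalence
    prevalence_concentration: float = 8.0  # Beta concentration of prevalences
    na_rate: float = 0.01               # P(spot pair unreadable) per clone/array
    n_excluded_target: int = 308        # clones planted to exceed the NA filter
    serum_noise_sd: float = 25.0        # between-serum latent spread (intensity units)
    duplicate_noise_sd: float = 5.0     # spot-level replicate noise
    array_offset_sd: float = 8.0        # additive array-wide offset (removed by QN)
    group_a_label: str = "NB"
    group_b_label: str = "WT"
    treatment: str = "untreated"
    max_na: int = 10                    # the downstream exclusion threshold
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_inframe <= self.n_clones):
            raise ValueError("need 0 < n_inframe <= n_clones")
        if self.n_informative > self.n_inframe:
            raise ValueError("n_informative must not exceed n_inframe")
        if min(self.n_sera_a, self.n_sera_b) < 2:
            raise ValueError("each group needs at least 2 sera (cross-validation)")
        for name in ("reactive_fraction_mean", "na_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.effect_shift < 0:
            raise ValueError("effect_shift must be >= 0")
        if self.n_excluded_target + self.n_informative > self.n_clones:
            raise ValueError("excluded + informative clones exceed n_clones")
        if self.n_excluded_target and self.max_na >= self.n_sera_a + self.n_sera_b:
            raise ValueError("cannot exceed the NA filter with so few arrays")


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated cohort: raw duplicate-spot profiles plus ground truth."""

    profiles: ProfileMatrix
    truth: pd.DataFrame  # index clone_id; columns: direction, effect_shift
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def planted_ids(self) -> list[str]:
        return self.truth.index.tolist()


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort from the latent-intensity model.

    All randomness flows from one :func:`numpy.random.default_rng` stream
    seeded with ``config.seed``; identical configs give bit-identical
    cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_clones, n_sera = config.n_clones, config.n_sera_a + config.n_sera_b

    clone_ids = np.array([f"SYNC{i:05d}" for i in range(n_clones)])
    serum_ids = [f"A{i:03d}" for i in range(config.n_sera_a)] + [
        f"B{i:03d}" for i in range(config.n_sera_b)
    ]
    group = np.array(
        [config.group_a_label] * config.n_sera_a + [config.group_b_label] * config.n_sera_b
    )
    in_frame = np.zeros(n_clones, dtype=bool)
    in_frame[rng.choice(n_clones, size=config.n_inframe, replace=False)] = True

    # planted markers among in-frame clones; NA-excluded clones among the rest
    inframe_idx = np.flatnonzero(in_frame)
    informative_idx = rng.choice(inframe_idx, size=config.n_informative, replace=False)
    pool = np.setdiff1d(np.arange(n_clones), informative_idx)
    excluded_idx = rng.choice(pool, size=config.n_excluded_target, replace=False)

    # per-clone prevalence -> baseline so that P(latent > 50) = prevalence
    m = config.reactive_fraction_mean
    k = config.prevalence_concentration
    prevalence = rng.beta(k * m, k * (1.0 - m), size=n_clones)
    baseline = 50.0 + config.serum_noise_sd * stats.norm.ppf(prevalence)

    latent = baseline[:, None] + rng.normal(0.0, config.serum_noise_sd, (n_clones, n_sera))
    latent[np.ix_(informative_idx, group == config.group_a_label)] += config.effect_shift
    latent += rng.normal(0.0, config.array_offset_sd, size=n_sera)[None, :]

    # duplicate spots: two noisy draws around the latent clone/serum value
    spots = latent[:, None, :] + rng.normal(
        0.0, config.duplicate_noise_sd, (n_clones, 2, n_sera)
    )
    spots = np.clip(np.rint(spots), INTENSITY_MIN, INTENSITY_MAX)

    na_cells = _draw_na_cells(rng, config, excluded_idx, n_clones, n_sera)
    spots[na_cells[:, None, :].repeat(2, axis=1)] = np.nan

    row_index = pd.Index(np.repeat(clone_ids, 2), name="clone_id")
    values = pd.DataFrame(
        spots.reshape(n_clones * 2, n_sera), index=row_index, columns=serum_ids
    )
    clones = pd.DataFrame(
        {"in_frame": in_frame, "antigen_name": ""},
        index=pd.Index(clone_ids, name="clone_id"),
    )
    sera = pd.DataFrame(
        {"group": group, "treatment": config.treatment},
        index=pd.Index(serum_ids, name="serum_id"),
    )
    profiles = ProfileMatrix(values=values, clones=clones, sera=sera, stage="raw_duplicates")

    truth = pd.DataFrame(
        {
            "direction": f"{config.group_a_label}-reactive",
            "effect_shift": config.effect_shift,
        },
        index=pd.Index(np.sort(clone_ids[informative_idx]), name="clone_id"),
    )
    return SyntheticCohort(profiles=profiles, truth=truth, config=config)


def _draw_na_cells(
    rng: np.random.Generator,
    config: SyntheticConfig,
    excluded_idx: np.ndarray,
    n_clones: int,
    n_sera: int,
) -> np.ndarray:
    """Boolean clone x serum mask of unreadable spot pairs.

    Background clones draw their NA count Binomial(n_sera, na_rate),
    capped at ``max_na`` so the exclusion count is exactly
    ``n_excluded_target`` (with the default na_rate the cap essentially
    never binds).  Planted excluded clones draw a count uniformly in
    (max_na, n_sera].
    """
    na = np.zeros((n_clones, n_sera), dtype=bool)
    counts = rng.binomial(n_sera, config.na_rate, size=n_clones)
    counts = np.minimum(counts, config.max_na)
    counts[excluded_idx] = rng.integers(
        config.max_na + 1, n_sera + 1, size=len(excluded_idx)
    )
    for i in np.flatnonzero(counts):
        na[i, rng.choice(n_sera, size=counts[i], replace=False)] = True
    return na
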