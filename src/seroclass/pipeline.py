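"""End-to-end pipeline: load or simulate profiles, average duplicates,
filter and impute NAs, quantile-normalize, then profile seroreactivity,
rank clones by AUC, and classify the serum groups.

The pipeline is configured by a single :class:`PipelineConfig` (loadable
from YAML) and writes a report bundle: reactivity table, frequency
histograms, high-reactivity overlap, clone scores, AUC distribution,
classification report, and a run manifest recording seed and every
threshold so a run can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import CVConfig, cross_validate, permutation_runs
from .informativeness import AUC_HIGH, AUC_LOW, CloneScoring, score_all_clones
from .normalization import quantile_normalize
from .profiles import (
    ProfileMatrix,
    average_replicates,
    filter_na_clones,
    impute_missing,
    read_profiles,
    write_annotations,
    write_profiles,
)
from .seroreactivity import (
    REACTIVITY_THRESHOLD,
    binarize,
    frequency_histogram,
    high_reactivity_overlap,
    reactivity_frequencies,
)
from .synthetic import SyntheticCohort, SyntheticConfig, simulate_cohort

log = logging.getLogger("seroclass")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; every analysis threshold is explicit."""

    matrix_path: str | None = None
    clone_annot_path: str | None = None
    serum_annot_path: str | None = None
    synthetic: SyntheticConfig | None = None
    group_a: str = "NB"
    group_b: str = "WT"
    max_na: int = 10
    reactivity_threshold: float = REACTIVITY_THRESHOLD
    auc_low: float = AUC_LOW
    auc_high: float = AUC_HIGH
    overlap_cutoff: float = 0.9
    cv: CVConfig = field(default_factory=CVConfig)
    run_classification: bool = True
    run_permutations: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and self.matrix_path is None:
            raise ValueError("config needs either input paths or a synthetic block")
        if self.synthetic is not None:
            self.synthetic.validate()
        self.cv.validate()
        if not 0 <= self.reactivity_threshold <= 255:
            raise ValueError("reactivity_threshold must be on the 0-255 scale")
        if not 0 <= self.auc_low <= self.auc_high <= 1:
            raise ValueError("AUC cut-offs must satisfy 0 <= low <= high <= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from YAML (nested blocks for cv/synthetic)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
    if "cv" in raw and raw["cv"] is not None:
        raw["cv"] = CVConfig(**raw["cv"])
    return PipelineConfig(**raw)


@dataclass(frozen=True)
class PipelineResult:
    """In-memory results of one pipeline run."""

    normalized: ProfileMatrix
    excluded_clones: list[str]
    n_imputed: int
    scoring: CloneScoring
    reactivity: pd.DataFrame
    histograms: dict[str, pd.DataFrame]
    overlap: pd.DataFrame
    classification: dict | None
    permutation: dict | None
    truth: pd.DataFrame | None


def prepare_matrix(
    m: ProfileMatrix, max_na: int = 10
) -> tuple[ProfileMatrix, list[str], int]:
    """Raw duplicates -> averaged -> NA-filtered -> imputed -> normalized."""
    if m.stage == "raw_duplicates":
        m = average_replicates(m)
    m, excluded = filter_na_clones(m, max_na=max_na)
    m, n_imputed = impute_missing(m)
    return quantile_normalize(m), excluded, n_imputed


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis; optionally write the report bundle."""
    cfg.validate()
    t0 = time.perf_counter()
    truth = None
    if cfg.synthetic is not None:
        cohort: SyntheticCohort = simulate_cohort(cfg.synthetic)
        m, truth = cohort.profiles, cohort.truth
        log.info("simulated cohort: %d clones x %d sera", m.n_clones, m.n_sera)
    else:
        m = read_profiles(cfg.matrix_path, cfg.clone_annot_path, cfg.serum_annot_path)
        log.info("loaded %s: %d clones x %d sera", cfg.matrix_path, m.n_clones, m.n_sera)

    norm, excluded, n_imputed = prepare_matrix(m, max_na=cfg.max_na)
    log.info(
        "excluded %d clones (>%d NAs), imputed %d cells, %d clones retained",
        len(excluded), cfg.max_na, n_imputed, norm.n_clones,
    )

    binary = binarize(norm, threshold=cfg.reactivity_threshold)
    rt = reactivity_frequencies(binary, norm)
    histograms = {g: frequency_histogram(rt, g) for g in rt.group_labels}
    overlap = high_reactivity_overlap(rt, cutoff=cfg.overlap_cutoff)

    scoring = score_all_clones(norm, group_a=cfg.group_a, group_b=cfg.group_b)
    log.info("scored %d clones; %d informative", len(scoring.scores),
             int(scoring.scores["informative"].sum()))

    classification = permutation = None
    if cfg.run_classification:
        report = cross_validate(norm, cfg.cv)
        classification = report.to_dict()
        log.info("CV accuracy %.3f", report.means["accuracy"])
        if cfg.run_permutations and cfg.cv.n_permutation_runs:
            perm = permutation_runs(norm, cfg.cv, observed_accuracy=report.means["accuracy"])
            permutation = {
                "accuracies": perm.accuracies.tolist(),
                "mean": perm.mean,
                "sd": perm.sd,
                "p_value": perm.p_value,
            }
            log.info("permuted accuracy %.3f +- %.3f", perm.mean, perm.sd)

    result = PipelineResult(
        normalized=norm,
        excluded_clones=excluded,
        n_imputed=n_imputed,
        scoring=scoring,
        reactivity=pd.concat([rt.frequencies, rt.counts], axis=1),
        histograms=histograms,
        overlap=overlap,
        classification=classification,
        permutation=permutation,
        truth=truth,
    )
    if out_dir is not None:
        _write_bundle(result, cfg, Path(out_dir), time.perf_counter() - t0)
    return result


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    return obj


def _write_bundle(result: PipelineResult, cfg: PipelineConfig, out: Path, elapsed: float) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_profiles(result.normalized, out / "matrix.norm.tsv")
    write_annotations(result.normalized, out / "clones.tsv", out / "sera.tsv")
    result.reactivity.to_csv(out / "reactivity.tsv", sep="\t", index_label="clone_id")
    for g, hist in result.histograms.items():
        hist.to_csv(out / f"frequency_histogram_{g}.tsv", sep="\t", index=False)
    result.overlap.to_csv(out / "high_reactivity_overlap.tsv", sep="\t",
                          index_label="clone_id")
    result.scoring.scores.to_csv(out / "clone_scores.tsv", sep="\t",
                                 index_label="clone_id")
    result.scoring.auc_distribution.to_csv(out / "auc_distribution.tsv", sep="\t",
                                           index=False)
    informative = result.scoring.scores[result.scoring.scores["informative"]]
    informative.sort_values("auc").to_csv(out / "informative_clones.tsv", sep="\t",
                                          index_label="clone_id")
    (out / "excluded_clones.txt").write_text(
        "".join(f"{c}\n" for c in result.excluded_clones)
    )
    report = {"classification": result.classification, "permutation": result.permutation}
    (out / "classification.json").write_text(json.dumps(report, indent=2) + "\n")
    if result.truth is not None:
        result.truth.to_csv(out / "planted_truth.tsv", sep="\t", index_label="clone_id")
    manifest = {
        "seroclass_version": __version__,
        "config": _jsonable(cfg),
        "n_excluded": len(result.excluded_clones),
        "n_imputed": result.n_imputed,
        "n_clones_retained": int(result.normalized.n_clones),
        "elapsed_seconds": round(elapsed, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
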