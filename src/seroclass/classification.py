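"""Linear-SVM group classification with repeated cross-validation and
permutation null runs.

The classifier is a linear-kernel support vector machine trained on the
normalized clone intensities (sera as samples, clones as features).
Performance is estimated by repeated stratified k-fold cross-validation:
within each repetition every serum is predicted exactly once, the
repetition's confusion counts are pooled, and accuracy / sensitivity /
specificity are averaged over repetitions with normal-theory 95%
confidence intervals.  Predictive values and likelihood ratios come from
the confusion counts pooled over all repetitions.  Overtraining is probed
by re-running the cross-validation with randomly permuted class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .profiles import ProfileMatrix, _require_stage

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings.

    ``positive_group`` is the label treated as the positive class in
    sensitivity/PPV etc. (Wilms tumor by default, matching the ROC
    convention of the per-clone AUC analysis).
    """

    n_repetitions: int = 20
    n_folds: int = 10
    n_permutation_runs: int = 20
    positive_group: str = "WT"
    svm_cost: float = 1.0
    seed: int = 0

    def validate(self, class_counts: dict[str, int] | None = None) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1 or self.n_permutation_runs < 0:
            raise ValueError("repetition counts must be positive")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be > 0")
        if class_counts is not None:
            smallest = min(class_counts.values())
            if len(class_counts) != 2:
                raise ValueError(f"need exactly two classes, got {class_counts}")
            if smallest < 2:
                raise ValueError("each class needs >= 2 sera")
            if self.n_folds > sum(class_counts.values()):
                raise ValueError("more folds than sera")


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Diagnostic panel from confusion counts.

    accuracy=(TP+TN)/N, sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    PPV=TP/(TP+FP), NPV=TN/(TN+FN), LR+=sens/(1-spec), LR-=(1-sens)/spec.
    Undefined ratios follow the usual conventions: a denominator of zero
    yields NaN, except LR+ which is +inf at perfect specificity.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "lr_pos": lr_pos,
        "lr_neg": lr_neg,
    }


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios from sensitivity/specificity.

    LR+ = sens/(1-spec) (+inf when specificity is 1); LR- = (1-sens)/spec
    (NaN when specificity is 0).
    """
    lr_pos = (
        float("inf") if specificity == 1.0 else sensitivity / (1.0 - specificity)
    )
    lr_neg = (1.0 - sensitivity) / specificity if specificity else float("nan")
    return lr_pos, lr_neg


@dataclass(frozen=True)
class ClassificationReport:
    """Aggregated repeated-CV metrics.

    ``means``/``ci_low``/``ci_high`` cover accuracy, sensitivity and
    specificity over repetitions; ``pooled`` is the diagnostic panel from
    confusion counts pooled over all repetitions.
    """

    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    pooled: dict[str, float]
    pooled_counts: dict[str, int]
    per_repetition: pd.DataFrame
    config: CVConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "means": self.means,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pooled": self.pooled,
            "pooled_counts": self.pooled_counts,
        }


@dataclass(frozen=True)
class PermutationSummary:
    """Null accuracies from permuted-label cross-validation runs."""

    accuracies: np.ndarray
    mean: float
    sd: float
    p_value: float | None  # empirical p of the observed accuracy, if given


def _design(m: ProfileMatrix, positive_group: str) -> tuple[np.ndarray, np.ndarray]:
    _require_stage(m, "normalized", "cross_validate")
    X = m.values.to_numpy(dtype=float).T  # sera x clones
    y = (m.groups().to_numpy() == positive_group).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"positive group {positive_group!r} missing or exhaustive")
    return X, y


def _cv_confusion(
    X: np.ndarray, y: np.ndarray, cfg: CVConfig, random_state: int
) -> tuple[int, int, int, int]:
    """One stratified k-fold pass; returns pooled (tp, fp, tn, fn)."""
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=random_state)
    tp = fp = tn = fn = 0
    for train, test in skf.split(X, y):
        clf = SVC(kernel="linear", C=cfg.svm_cost)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return tp, fp, tn, fn


def cross_validate(m: ProfileMatrix, cfg: CVConfig) -> ClassificationReport:
    """Repeated stratified k-fold cross-validation of the linear SVM.

    Stratification guarantees both classes in every training split for
    the unbalanced cohorts this analysis targets.  The report is
    bit-identical for a fixed config and seed.
    """
    X, y = _design(m, cfg.positive_group)
    counts = pd.Series(y).value_counts().to_dict()
    cfg.validate({str(k): v for k, v in counts.items()})
    rep_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_repetitions) % (2**31)

    rows = []
    pooled = np.zeros(4, dtype=int)
    for rep, rs in enumerate(rep_seeds):
        tp, fp, tn, fn = _cv_confusion(X, y, cfg, int(rs))
        pooled += (tp, fp, tn, fn)
        panel = diagnostic_metrics(tp, fp, tn, fn)
        rows.append(
            {
                "repetition": rep,
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                "accuracy": panel["accuracy"],
                "sensitivity": panel["sensitivity"],
                "specificity": panel["specificity"],
            }
        )
    per_rep = pd.DataFrame(rows).set_index("repetition")

    means, lo, hi = {}, {}, {}
    for metric in ("accuracy", "sensitivity", "specificity"):
        vals = per_rep[metric].to_numpy()
        mu = float(vals.mean())
        half = _Z95 * float(vals.std(ddof=1)) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        means[metric], lo[metric], hi[metric] = mu, mu - half, mu + half
    tp, fp, tn, fn = (int(v) for v in pooled)
    return ClassificationReport(
        means=means,
        ci_low=lo,
        ci_high=hi,
        pooled=diagnostic_metrics(tp, fp, tn, fn),
        pooled_counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        per_repetition=per_rep,
        config=cfg,
    )


def permutation_runs(
    m: ProfileMatrix, cfg: CVConfig, observed_accuracy: float | None = None
) -> PermutationSummary:
    """Permuted-label null runs.

    Each run permutes the class labels once (class sizes preserved) and
    executes one full stratified k-fold cross-validation; the run's
    pooled accuracy estimates chance-level performance.  When
    ``observed_accuracy`` is supplied, the empirical p-value
    (1 + #{runs >= observed}) / (n_runs + 1) is reported.
    """
    X, y = _design(m, cfg.positive_group)
    counts = pd.Series(y).value_counts().to_dict()
    cfg.validate({str(k): v for k, v in counts.items()})
    ss = np.random.SeedSequence([cfg.seed, 1]).generate_state(2 * cfg.n_permutation_runs)
    ss = ss % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    accs = np.empty(cfg.n_permutation_runs)
    for run in range(cfg.n_permutation_runs):
        y_perm = rng.permutation(y)
        tp, fp, tn, fn = _cv_confusion(X, y_perm, cfg, int(ss[run]))
        accs[run] = (tp + tn) / (tp + fp + tn + fn)
    p = None
    if observed_accuracy is not None:
        p = (1 + int(np.sum(accs >= observed_accuracy))) / (cfg.n_permutation_runs + 1)
    return PermutationSummary(
        accuracies=accs,
        mean=float(accs.mean()),
        sd=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        p_value=p,
    )
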