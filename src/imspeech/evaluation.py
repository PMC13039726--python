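"""Leakage-aware evaluation: three split strategies, metrics, statistics.

Strategy 1 (``random_multiseed``): stratified 90/10 window-level splits
repeated across seeds {1..5}; overlapping windows are allowed, so this is
the optimistic upper-bound protocol (temporal leakage is tolerated by
design).

Strategy 2 (``group_kfold``): stratified 10-fold cross-validation over
non-overlapping windows; entire windows belong to exactly one fold and
non-overlapping segmentation guarantees no raw sample is shared between
folds, eliminating temporal leakage (subject leakage remains).

Strategy 3 (``loso_calibrated``): leave-one-subject-out with a calibration
phase — 20% of the held-out subject's windows (stratified by class)
fine-tune the pretrained model, the remaining 80% are test-only.

The metric suite reports accuracy, weighted precision/F1, per-class recall,
macro F1, and balanced accuracy (the mean of per-class recalls), all derived
from the confusion matrix.  Statistical comparisons use 95% Student-t
confidence margins, Welch's t recovered from reported mean +/- margin
summaries, and Cohen's d under the independent-equal-n (d = t*sqrt(2/n)) and
paired (d = t/sqrt(n)) conventions.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .models import (
    ArchitectureSpec,
    ModelHandle,
    TrainingConfig,
    build_model,
    fine_tune,
    predict,
    train_model,
)
from .preprocess import SpecError, WindowSet, apply_normalizer, fit_normalizer

STRATEGIES = ("random_multiseed", "group_kfold", "loso_calibrated")
DEFAULT_SEEDS = (1, 2, 3, 4, 5)


class LeakageError(RuntimeError):
    """A split would share raw samples or subjects where forbidden."""


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    fold_id: str
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    calib_idx: np.ndarray | None = None

    def roles_partition(self, n: int) -> bool:
        parts = [self.train_idx, self.test_idx]
        if self.calib_idx is not None:
            parts.append(self.calib_idx)
        cat = np.concatenate(parts)
        return len(cat) == n and len(np.unique(cat)) == n


@dataclass(frozen=True)
class SplitPlan:
    strategy: str
    folds: tuple[Fold, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise SpecError(f"unknown strategy {self.strategy!r}")


def make_random_splits(ws: WindowSet, seeds: Sequence[int] = DEFAULT_SEEDS,
                       test_frac: float = 0.10) -> SplitPlan:
    """Strategy 1: one stratified window-level 90/10 partition per seed."""
    from sklearn.model_selection import StratifiedShuffleSplit

    if not 0 < test_frac < 1:
        raise SpecError(f"test_frac must be in (0, 1), got {test_frac}")
    counts = np.bincount(ws.labels)
    need = int(np.ceil(1 / test_frac))
    if counts[counts > 0].min() < need:
        raise SpecError(f"every class needs >= {need} windows for "
                        f"test_frac={test_frac}")
    folds = []
    for seed in seeds:
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_frac,
                                          random_state=seed)
        train_idx, test_idx = next(splitter.split(ws.windows[:, 0, 0, None],
                                                  ws.labels))
        folds.append(Fold(f"seed{seed}", int(seed), np.sort(train_idx),
                          np.sort(test_idx)))
    return SplitPlan("random_multiseed", tuple(folds),
                     {"test_frac": test_frac, "seeds": tuple(seeds)})


def make_group_kfold(ws: WindowSet, k: int = 10, group_key: str = "window",
                     *, seed: int = 0,
                     strict: bool = True) -> SplitPlan:
    """Strategy 2: stratified k-fold with a configurable grouping atom.

    ``group_key='window'`` (the default) assigns whole windows to folds;
    combined with non-overlapping segmentation this removes temporal
    leakage.  ``'recording'``/``'subject'`` keep all windows of a group in
    one fold.  In strict mode overlapping window schemes are refused.
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    if group_key not in ("window", "recording", "subject"):
        raise SpecError(f"unknown group_key {group_key!r}")
    if strict and ws.scheme.overlapping:
        raise LeakageError(
            "temporal leakage: overlapping windows (scheme "
            f"{ws.scheme.name!r}, ws={ws.scheme.ws}, stride={ws.scheme.stride}) "
            "share raw samples across folds; use non-overlapping Scheme B"
        )
    if group_key == "window":
        if k > len(ws):
            raise SpecError(f"k={k} exceeds {len(ws)} windows")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(len(ws)), ws.labels)
    else:
        groups = ws.recording_ids if group_key == "recording" else ws.subject_ids
        if k > len(np.unique(groups)):
            raise SpecError(f"k={k} exceeds {len(np.unique(groups))} groups")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        iterator = splitter.split(np.zeros(len(ws)), ws.labels, groups)
    folds = tuple(
        Fold(f"fold{i}", seed, np.sort(tr), np.sort(te))
        for i, (tr, te) in enumerate(iterator)
    )
    return SplitPlan("group_kfold", folds,
                     {"k": k, "group_key": group_key, "seed": seed})


def make_loso_folds(ws: WindowSet, calib_frac: float = 0.20,
                    seed: int = 0, *,
                    strict: bool = True) -> SplitPlan:
    """Strategy 3: one fold per subject, with a stratified calibration split.

    Each held-out subject's windows are divided into ``calib_frac``
    calibration and the remainder test; all other subjects' windows train.
    """
    from sklearn.model_selection import train_test_split

    subjects = np.unique(ws.subject_ids)
    if len(subjects) < 2:
        raise SpecError("LOSO requires at least 2 subjects")
    if strict and ws.scheme.overlapping:
        raise LeakageError(
            "temporal leakage: LOSO in strict mode requires "
            "non-overlapping Scheme B windows"
        )
    folds = []
    for subject in subjects:
        held = np.flatnonzero(ws.subject_ids == subject)
        train_idx = np.flatnonzero(ws.subject_ids != subject)
        held_labels = ws.labels[held]
        present, counts = np.unique(held_labels, return_counts=True)
        if counts.min() < 2:
            raise SpecError(
                f"subject {subject!r} has a class with fewer than 2 windows; "
                "cannot stratify calibration"
            )
        calib, test = train_test_split(held, train_size=calib_frac,
                                       stratify=held_labels,
                                       random_state=seed)
        folds.append(Fold(f"loso_{subject}", seed, train_idx,
                          np.sort(test), np.sort(calib)))
    return SplitPlan("loso_calibrated", tuple(folds),
                     {"calib_frac": calib_frac, "seed": seed})


def audit_leakage(ws: WindowSet, fold: Fold) -> None:
    """Hard check: no raw sample of any test window is reachable from train.

    Two windows of the same recording leak if their [start, start+ws) sample
    spans intersect.  LOSO folds additionally require the test and
    calibration windows to share exactly one subject absent from training.
    """
    w = ws.scheme.ws
    train_spans: dict[str, list[tuple[int, int]]] = {}
    for i in fold.train_idx:
        train_spans.setdefault(ws.recording_ids[i], []).append(
            (int(ws.starts[i]), int(ws.starts[i]) + w))
    for i in fold.test_idx:
        rid = ws.recording_ids[i]
        if rid not in train_spans:
            continue
        s, e = int(ws.starts[i]), int(ws.starts[i]) + w
        for ts, te in train_spans[rid]:
            if s < te and ts < e:
                raise LeakageError(
                    f"fold {fold.fold_id!r}: test window [{s}, {e}) of "
                    f"recording {rid!r} overlaps train window [{ts}, {te})"
                )
    if fold.calib_idx is not None:
        held = set(ws.subject_ids[fold.test_idx]) | set(
            ws.subject_ids[fold.calib_idx])
        if len(held) != 1:
            raise LeakageError(
                f"fold {fold.fold_id!r}: test+calibration span subjects "
                f"{sorted(held)}, expected exactly one"
            )
        if held & set(ws.subject_ids[fold.train_idx]):
            raise LeakageError(
                f"fold {fold.fold_id!r}: held-out subject appears in training"
            )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise SpecError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] != len(self.class_labels):
            raise SpecError("class label count does not match matrix size")
        if np.any(counts < 0):
            raise SpecError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         class_labels: Sequence[str]) -> "ConfusionMatrix":
        c = len(class_labels)
        counts = np.zeros((c, c), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
        return cls(counts, tuple(class_labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    weighted_precision: float
    per_class_recall: np.ndarray
    weighted_f1: float
    macro_f1: float
    balanced_accuracy: float
    support: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy,
                "weighted_precision": self.weighted_precision,
                "weighted_f1": self.weighted_f1,
                "macro_f1": self.macro_f1,
                "balanced_accuracy": self.balanced_accuracy}


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All summary metrics from one confusion matrix.

    Zero-support classes are excluded from macro averages (with a warning)
    and reported as NaN per-class.
    """
    counts = cm.counts.astype(float)
    n = counts.sum()
    if n < 1:
        raise SpecError("empty confusion matrix")
    tp = np.diag(counts)
    support = counts.sum(axis=1)          # n_i: true samples per class
    predicted = counts.sum(axis=0)        # tp_i + fp_i
    w = support / n
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, np.nan)
        pr_sum = precision + np.nan_to_num(recall)
        f1 = np.where(pr_sum > 0, 2 * precision * np.nan_to_num(recall) / pr_sum, 0.0)
    has_support = support > 0
    if not np.all(has_support):
        warnings.warn(
            f"classes with zero support excluded from macro averages: "
            f"{[cm.class_labels[i] for i in np.flatnonzero(~has_support)]}",
            stacklevel=2,
        )
    accuracy = float(tp.sum() / n)
    return MetricReport(
        accuracy=accuracy,
        weighted_precision=float(np.sum(w * precision)),
        per_class_recall=recall,
        weighted_f1=float(np.sum(w * f1)),
        macro_f1=float(np.mean(f1[has_support])),
        balanced_accuracy=float(np.mean(recall[has_support])),
        support=support.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def ci_margin(values: Sequence[float], level: float = 0.95) -> float:
    """Student-t margin of error: t_crit(level, n-1) * sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for a confidence margin")
    t_crit = sp_stats.t.ppf(0.5 + level / 2, df=n - 1)
    return float(t_crit * values.std(ddof=1) / np.sqrt(n))


def welch_t_from_summary(mean1: float, margin1: float, mean2: float,
                         margin2: float, n: int,
                         level: float = 0.95) -> tuple[float, float]:
    """Welch's t and Welch-Satterthwaite df from mean +/- margin summaries.

    The margins must be ``ci_margin``-style 95% values with the same group
    size n; each group's sd is recovered as margin*sqrt(n)/t_crit.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if margin1 <= 0 or margin2 <= 0:
        raise ValueError("margins must be positive")
    t_crit = sp_stats.t.ppf(0.5 + level / 2, df=n - 1)
    sd1 = margin1 * np.sqrt(n) / t_crit
    sd2 = margin2 * np.sqrt(n) / t_crit
    se_sq1, se_sq2 = sd1 ** 2 / n, sd2 ** 2 / n
    t = (mean1 - mean2) / np.sqrt(se_sq1 + se_sq2)
    df = (se_sq1 + se_sq2) ** 2 / (
        se_sq1 ** 2 / (n - 1) + se_sq2 ** 2 / (n - 1))
    return float(t), float(df)


def cohen_d(t: float, n: int, design: str = "independent_equal_n") -> float:
    """Effect size from a t statistic.

    ``independent_equal_n``: d = t * sqrt(2/n); ``paired``: d = t / sqrt(n).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if design == "independent_equal_n":
        return float(t * np.sqrt(2.0 / n))
    if design == "paired":
        return float(t / np.sqrt(n))
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# Strategy runner
# ---------------------------------------------------------------------------

@dataclass
class ResultTable:
    """Per-fold metric reports plus aggregates and breakdowns."""

    strategy: str
    per_fold: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]          # metric -> (mean, margin)
    confusions: list[ConfusionMatrix]
    per_subject: pd.DataFrame
    per_class_recall: pd.DataFrame

    def summary_markdown(self) -> str:
        lines = [f"### Strategy: {self.strategy}", "",
                 "| metric | mean | ±95% CI |", "|---|---|---|"]
        for metric, (mean, margin) in self.aggregate.items():
            lines.append(f"| {metric} | {100 * mean:.2f}% | {100 * margin:.2f} |")
        return "\n".join(lines)


def run_strategy(ws: WindowSet, plan: SplitPlan, arch: ArchitectureSpec,
                 cfg: TrainingConfig, *, calibrate: bool = True,
                 sd_floor: float = 1e-8,
                 audit: bool = True) -> ResultTable:
    """Train/evaluate one architecture under one split plan.

    Per fold: fit normalization statistics on the fold's training windows
    only, train a freshly initialised model (fold-varied seed), optionally
    fine-tune on the calibration windows (LOSO), predict, and score.  With
    ``audit`` every fold passes the temporal/subject leakage audit first
    (non-overlapping schemes only; Strategy 1 sets ``audit=False`` since it
    tolerates temporal leakage by design).
    """
    if ws.normalized:
        raise SpecError("run_strategy expects unnormalized windows; "
                        "normalization is fit per fold")
    rows, confusions, subj_rows = [], [], []
    recalls = []
    for fold in plan.folds:
        if not fold.roles_partition(len(ws)):
            raise SpecError(f"fold {fold.fold_id!r} roles do not partition "
                            "the window set")
        if audit and plan.strategy != "random_multiseed":
            audit_leakage(ws, fold)
        train_ws = ws.subset(fold.train_idx)
        test_ws = ws.subset(fold.test_idx)
        stats = fit_normalizer(train_ws, sd_floor)
        train_n = apply_normalizer(stats, train_ws)
        test_n = apply_normalizer(stats, test_ws)
        fold_tag = zlib.crc32(fold.fold_id.encode()) % 997
        fold_cfg = replace(cfg, seed=(cfg.seed + fold.seed * 1009 + fold_tag)
                           % (2 ** 31 - 1))
        model = build_model(arch, ws.windows.shape[1:3], init_seed=fold_cfg.seed)
        model, _ = train_model(model, train_n, fold_cfg)
        if calibrate and fold.calib_idx is not None and len(fold.calib_idx):
            calib_n = apply_normalizer(stats, ws.subset(fold.calib_idx))
            model, _ = fine_tune(model, calib_n, replace(fold_cfg, batch_size=128))
        y_pred, _ = predict(model, test_n)
        cm = ConfusionMatrix.from_predictions(test_n.labels, y_pred,
                                              ws.class_labels)
        report = compute_metrics(cm)
        confusions.append(cm)
        recalls.append(report.per_class_recall)
        rows.append({"fold": fold.fold_id, "seed": fold.seed,
                     "n_test": len(test_n), **report.as_dict()})
        for subject in np.unique(test_n.subject_ids):
            mask = test_n.subject_ids == subject
            subj_rows.append({
                "fold": fold.fold_id, "subject": subject,
                "accuracy": float(np.mean(y_pred[mask] == test_n.labels[mask])),
                "n": int(mask.sum()),
            })
    per_fold = pd.DataFrame(rows)
    metrics = ["accuracy", "balanced_accuracy", "macro_f1",
               "weighted_precision", "weighted_f1"]
    aggregate = {}
    for metric in metrics:
        vals = per_fold[metric].to_numpy()
        margin = ci_margin(vals) if len(vals) >= 2 else 0.0
        aggregate[metric] = (float(vals.mean()), margin)
    per_class = pd.DataFrame(np.vstack(recalls), columns=list(ws.class_labels))
    return ResultTable(plan.strategy, per_fold, aggregate, confusions,
                       pd.DataFrame(subj_rows), per_class)
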