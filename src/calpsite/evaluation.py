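"""Confusion-matrix metrics, ROC/AUC, k-fold cross-validation, and the flank sweep.

Metric definitions follow the usual confusion-matrix forms:
Sn = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP), Ac = (TP+TN)/total.
The ROC curve sweeps every score threshold; its trapezoidal area equals the
Mann-Whitney U statistic normalized by n_pos * n_neg (ties contribute 1/2).

Cross-validation is stratified: with a handful of true cleavage sites among
tens of thousands of candidate bonds, unstratified folds could easily starve
a fold of positives.  The per-position frequency profile is refit on each
training fold — it is part of the model, so fitting it on held-out windows
would leak label information into the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoders import FrequencyProfile, fit_frequency_profile
from .nn import Hyperparameters, TrainedModel, train
from .sequence_io import CleavageSite, LabeledDataset, Protein, build_dataset


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts at a score threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, precision and accuracy; ``None`` where undefined."""

    sn: float | None
    sp: float | None
    pr: float | None
    ac: float


def confusion_metrics(counts: ConfusionCounts) -> Metrics:
    """Sn/Sp/Pr/Ac from confusion counts; a zero denominator flags that metric ``None``."""
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    sn = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    pr = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    ac = (counts.tp + counts.tn) / counts.total
    return Metrics(sn=sn, sp=sp, pr=pr, ac=ac)


def counts_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Binarize scores at ``threshold`` (score >= threshold is a predicted site)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def threshold_for_specificity(
    scores: np.ndarray, labels: np.ndarray, target_sp: float
) -> float:
    """Smallest threshold achieving at least ``target_sp`` specificity on the given data."""
    neg = np.sort(np.asarray(scores, dtype=float)[np.asarray(labels) == 0])
    if len(neg) == 0:
        raise ValueError("no negative scores to calibrate against")
    # specificity at threshold t is the fraction of negatives strictly below t
    k = int(np.ceil(target_sp * len(neg)))
    if k >= len(neg):
        return float(np.nextafter(neg[-1], np.inf))
    return float(np.nextafter(neg[k - 1], np.inf)) if k > 0 else float("-inf")


@dataclass
class RocCurve:
    """ROC points (false-positive rate = 1-Sp, true-positive rate = Sn) and the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        ).to_csv(path, sep="\t", index=False)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve over all score thresholds with trapezoidal AUC.

    Tied scores collapse to a single threshold, so the AUC equals the
    normalized Mann-Whitney statistic P(score_pos > score_neg) + P(tie)/2.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires scores from both classes")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class FoldResult:
    """One cross-validation fold: index sets, per-fold profile, scores and metrics."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    profile: FrequencyProfile
    scores: np.ndarray
    labels: np.ndarray
    metrics: Metrics
    auc: float


@dataclass
class CVResult:
    """Stratified k-fold cross-validation output."""

    k: int
    seed: int
    folds: list[FoldResult]
    pooled_roc: RocCurve

    @property
    def pooled_auc(self) -> float:
        return self.pooled_roc.auc

    def report(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds, start=1):
            rows.append(
                {
                    "fold": str(i),
                    "n_test": len(f.test_indices),
                    "sn": f.metrics.sn,
                    "sp": f.metrics.sp,
                    "pr": f.metrics.pr,
                    "ac": f.metrics.ac,
                    "auc": f.auc,
                }
            )
        pooled_scores = np.concatenate([f.scores for f in self.folds])
        pooled_labels = np.concatenate([f.labels for f in self.folds])
        pooled = confusion_metrics(counts_from_scores(pooled_scores, pooled_labels))
        rows.append(
            {
                "fold": "pooled",
                "n_test": len(pooled_scores),
                "sn": pooled.sn,
                "sp": pooled.sp,
                "pr": pooled.pr,
                "ac": pooled.ac,
                "auc": self.pooled_auc,
            }
        )
        return pd.DataFrame(rows)


def kfold_cv(
    dataset: LabeledDataset,
    k: int,
    hyper: Hyperparameters | None = None,
    seed: int = 0,
    kmax: int = 3,
    threshold: float = 0.5,
    class_balance_mode: str = "balanced",
) -> CVResult:
    """Stratified k-fold cross-validation of the full train/score pipeline.

    Each fold refits the frequency profile and the network on the k-1
    training folds only, then scores the held-out fold.  Fold assignment and
    all training randomness derive from ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = dataset.labels
    n_pos, n_neg = dataset.n_positive, dataset.n_negative
    if min(n_pos, n_neg) < k:
        raise ValueError(f"k={k} exceeds the smaller class size {min(n_pos, n_neg)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold_i, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(labels)), labels)
    ):
        train_set = dataset.subset(train_idx)
        test_set = dataset.subset(test_idx)
        profile = fit_frequency_profile(train_set)
        trained = train(
            train_set,
            hyper=hyper,
            profile=profile,
            seed=seed * 1009 % (2**31) + fold_i,
            kmax=kmax,
            class_balance_mode=class_balance_mode,
        )
        scores = trained.predict_windows(test_set.windows)
        metrics = confusion_metrics(counts_from_scores(scores, test_set.labels, threshold))
        folds.append(
            FoldResult(
                train_indices=np.asarray(train_idx),
                test_indices=np.asarray(test_idx),
                profile=profile,
                scores=scores,
                labels=test_set.labels,
                metrics=metrics,
                auc=roc_auc(scores, test_set.labels).auc,
            )
        )
    pooled_scores = np.concatenate([f.scores for f in folds])
    pooled_labels = np.concatenate([f.labels for f in folds])
    pooled = roc_auc(pooled_scores, pooled_labels)
    return CVResult(k=k, seed=seed, folds=folds, pooled_roc=pooled)


def flank_sweep(
    proteins: Sequence[Protein],
    sites: Sequence[CleavageSite],
    flank_values: Sequence[int],
    k: int = 5,
    hyper: Hyperparameters | None = None,
    seed: int = 0,
    kmax: int = 3,
    negative_subsample: int | None = None,
) -> pd.DataFrame:
    """Pooled cross-validated AUC as a function of window flank size.

    Windows are re-extracted at each flank (encoder input dimensions adapt:
    AAC stays 21, BE is 42f, PSFM 4f, CKSAAP 441*(kmax+1)), then the same
    k-fold pipeline runs per flank.
    """
    if any(f < 1 for f in flank_values):
        raise ValueError("flank values must be >= 1")
    rows = []
    for flank in flank_values:
        dataset = build_dataset(
            proteins,
            sites,
            flank=flank,
            negative_subsample=negative_subsample,
            seed=seed,
        )
        cv = kfold_cv(dataset, k=k, hyper=hyper, seed=seed, kmax=kmax)
        rows.append({"flank": flank, "pooled_auc": cv.pooled_auc})
    return pd.DataFrame(rows)


def plot_roc(curves: dict[str, RocCurve], path: str | Path) -> None:
    """Write a ROC figure for one or more labeled curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC = {curve.auc:.4f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - Sp")
    ax.set_ylabel("Sn")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
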