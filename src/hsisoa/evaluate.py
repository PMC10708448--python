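"""Validation experiments and confusion-matrix reporting.

Overall accuracy (OA) is the trace of the confusion matrix over the
total count; the error rate is 1 - OA; per-class accuracy is the
diagonal over the row sum.  Two experiment protocols are provided:

* ``loo_experiment`` -- leave-one-out cross-validation of the one-vs-one
  ensemble on one day's (and optionally one round's) spectra.  Per
  class pair, hyperparameters are chosen by RMSEcv on the pair's rows;
  each pair row's voting probability comes from the fold model fitted
  without it (preprocessing refit per fold), and rows outside the pair
  are scored by the full-pair model, which never saw them -- no sample
  is ever scored by a model trained on it.
* ``day_to_day`` -- train a single ensemble on one day, predict another
  day's rows with every fitted parameter frozen, probing robustness to
  temporal drift.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import SVMGrid, _select, binary_probability, ovo_train, predict
from .preprocess import SpectraTable, preprocess_chain_apply
from .synthetic import canonical_order

__all__ = [
    "ConfusionReport",
    "confusion",
    "loo_experiment",
    "day_to_day",
    "exclude_outliers",
    "render_report",
    "report_from_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionReport:
    """K x K count matrix (rows = true, cols = predicted) with derived rates."""

    counts: np.ndarray
    classes: list[str]
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def error_rate(self) -> float:
        return 1.0 - self.overall_accuracy

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    @property
    def per_class_error(self) -> np.ndarray:
        return 1.0 - self.per_class_accuracy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str],
    descriptor: dict | None = None,
) -> ConfusionReport:
    """Tally a confusion report; unknown labels raise."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} not in class order")
        counts[index[t], index[p]] += 1
    return ConfusionReport(counts=counts, classes=list(classes), descriptor=descriptor or {})


def _usable_subset(
    table: SpectraTable,
    dat: int | Iterable[int] | None,
    rounds: int | Iterable[int] | None,
    drop_outliers: bool,
) -> SpectraTable:
    sub = table.filter(dat=dat, rounds=rounds, drop_outliers=drop_outliers)
    labels = sub.meta["treatment"]
    small = [c for c, n in labels.value_counts().items() if n < 2]
    if small:
        warnings.warn(f"classes {small} have < 2 samples and are skipped")
        sub = sub.select(~labels.isin(small).to_numpy())
    return sub


def loo_experiment(
    table: SpectraTable,
    learner: str = "svm",
    dat: int | Iterable[int] | None = None,
    rounds: int | Iterable[int] | None = None,
    class_order: Sequence[str] | None = None,
    grid: SVMGrid | None = None,
    max_lv: int = 3,
    drop_outliers: bool = True,
) -> ConfusionReport:
    """Leave-one-out OVO soft-voting cross-validation on the filtered rows."""
    sub = _usable_subset(table, dat, rounds, drop_outliers)
    labels = sub.meta["treatment"].to_numpy()
    order = list(class_order) if class_order is not None else canonical_order(np.unique(labels))
    n, k = len(sub), len(order)
    if k < 2:
        raise ValueError("need at least 2 classes for classification")
    col = {c: i for i, c in enumerate(order)}
    sums = np.zeros((n, k))
    for a, b in itertools.combinations(order, 2):
        in_pair = np.isin(labels, [a, b])
        Xp = sub.X[in_pair]
        yp = (labels[in_pair] == b).astype(int)
        model = _select(learner, Xp, yp, grid=grid, max_lv=max_lv)
        model.classes = (a, b)
        p = np.empty(n)
        p[in_pair] = model.cv_probabilities
        if np.any(~in_pair):
            Z = preprocess_chain_apply(sub.X[~in_pair], model.chain)
            p[~in_pair] = binary_probability(model, Z)
        sums[:, col[a]] += 1.0 - p
        sums[:, col[b]] += p
    averages = sums / (k - 1)
    pred = np.array([order[i] for i in np.argmax(averages, axis=1)])
    return confusion(
        labels,
        pred,
        order,
        descriptor={
            "experiment": "leave-one-out",
            "learner": learner,
            "dat": dat,
            "rounds": rounds,
            "cv": "loo; per-pair RMSEcv selection; fold probabilities for pair rows",
            "n": n,
        },
    )


def day_to_day(
    table: SpectraTable,
    train_dat: int | Iterable[int],
    test_dat: int | Iterable[int],
    learner: str = "svm",
    rounds: int | Iterable[int] | None = None,
    class_order: Sequence[str] | None = None,
    grid: SVMGrid | None = None,
    max_lv: int = 3,
    drop_outliers: bool = True,
) -> ConfusionReport:
    """Train on one day's spectra, test on another's, with all parameters frozen."""
    train = _usable_subset(table, train_dat, rounds, drop_outliers)
    test = table.filter(dat=test_dat, rounds=rounds, drop_outliers=drop_outliers)
    if len(test) == 0:
        raise ValueError("no test rows for the requested day")
    key_cols = ["sample_id", "dat"]
    overlap = pd.merge(train.meta[key_cols], test.meta[key_cols])
    if len(overlap):
        raise ValueError(
            f"protocol violation: {len(overlap)} identical (sample id, DAT) rows "
            "appear in both train and test"
        )
    train_classes = set(train.meta["treatment"])
    test_classes = set(test.meta["treatment"])
    unseen = test_classes - train_classes
    if unseen:
        raise ValueError(f"test day contains classes never trained on: {sorted(unseen)}")
    ensemble = ovo_train(train, learner=learner, class_order=class_order, grid=grid, max_lv=max_lv)
    pred, _ = predict(ensemble, test)
    return confusion(
        test.meta["treatment"],
        pred,
        ensemble.classes,
        descriptor={
            "experiment": "day-to-day",
            "learner": learner,
            "train_dat": train_dat,
            "test_dat": test_dat,
            "rounds": rounds,
            "n_train": len(train),
            "n_test": len(test),
        },
    )


def exclude_outliers(
    table: SpectraTable, sample_ids: Sequence[str] | None = None
) -> SpectraTable:
    """Remove flagged plants (or an explicit id list) across ALL days.

    Absent ids warn and are ignored; removal is logged.
    """
    if sample_ids is None:
        ids = sorted(table.meta.loc[table.meta["outlier"].astype(bool), "sample_id"].unique())
    else:
        ids = list(sample_ids)
        present = set(table.meta["sample_id"])
        for sid in ids:
            if sid not in present:
                warnings.warn(f"sample id {sid!r} not present; nothing to exclude")
        ids = [sid for sid in ids if sid in present]
    if not ids:
        return table
    keep = ~table.meta["sample_id"].isin(ids).to_numpy()
    logger.info("excluding %d outlier samples (%d rows): %s", len(ids), int((~keep).sum()), ids)
    return table.select(keep)


def render_report(report: ConfusionReport, out_dir: str, name: str = "confusion") -> dict:
    """Write the report as an annotated heatmap PNG, a CSV twin and a JSON descriptor.

    The CSV holds the K x K counts plus per-class accuracy and error
    columns; the heatmap title carries the overall accuracy.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    os.makedirs(out_dir, exist_ok=True)
    frame = report.to_frame()
    frame["accuracy"] = report.per_class_accuracy
    frame["error_rate"] = report.per_class_error
    csv_path = os.path.join(out_dir, f"{name}.csv")
    frame.to_csv(csv_path, index_label="true_class")

    k = len(report.classes)
    fig, axes = plt.subplots(
        1, 2, figsize=(1.0 * k + 5, 0.8 * k + 2), width_ratios=[k, 2], sharey=True
    )
    sns.heatmap(report.to_frame(), annot=True, fmt="d", cmap="Blues", cbar=False, ax=axes[0])
    rates = pd.DataFrame(
        {"accuracy": report.per_class_accuracy, "error": report.per_class_error},
        index=report.classes,
    )
    sns.heatmap(rates, annot=True, fmt=".2f", cmap="RdYlBu_r", vmin=0, vmax=1, cbar=False, ax=axes[1])
    axes[0].set_ylabel("true class")
    axes[0].set_xlabel("predicted class")
    fig.suptitle(f"OA = {report.overall_accuracy:.1%}")
    fig.tight_layout()
    png_path = os.path.join(out_dir, f"{name}.png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)

    json_path = os.path.join(out_dir, f"{name}.json")
    with open(json_path, "w") as fh:
        json.dump(
            {
                "overall_accuracy": report.overall_accuracy,
                "error_rate": report.error_rate,
                "classes": report.classes,
                "descriptor": report.descriptor,
            },
            fh,
            indent=2,
            default=str,
        )
    return {"csv": csv_path, "png": png_path, "json": json_path}


def report_from_csv(path: str) -> ConfusionReport:
    """Reconstruct a ConfusionReport from its CSV twin."""
    df = pd.read_csv(path, index_col="true_class")
    classes = [c for c in df.columns if c not in ("accuracy", "error_rate")]
    return ConfusionReport(counts=df[classes].to_numpy(dtype=int), classes=classes)
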