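"""Binary PLS-DA and SVM learners with RMSEcv selection and OVO soft voting.

The K-class site-of-action problem is decomposed into K(K-1)/2 binary
problems, one per unordered class pair.  Each binary learner is chosen
by the smallest leave-one-out cross-validated RMSE between its
predicted class-1 probability and the {0, 1} labels (RMSEcv): PLS-DA
over 1..3 latent variables, SVM over a log-spaced grid of C (1e-3..100)
and, for the RBF kernel, gamma (1e-6..1e-1), plus linear-kernel
candidates over the same C grid.  Ties prefer fewer latent variables,
respectively the linear kernel, then smaller C, then smaller gamma.

Probabilities: PLS-DA uses its continuous prediction clipped to [0, 1];
SVM uses a logistic (Platt-style) calibration of the decision value,
fitted on training rows.  Soft voting averages, for each class, the
probabilities from the K-1 binary models involving that class and
predicts the argmax (ties break toward the earlier class in canonical
order).

Each binary model owns a preprocessing chain (log(1/R) -> MSC -> mean
centering) fitted on its own training rows and applied, frozen, to any
spectrum it is asked to score.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .preprocess import (
    PreprocessModel,
    SpectraTable,
    log_inverse,
    msc_apply,
    preprocess_chain_apply,
    preprocess_chain_fit,
)
from .synthetic import canonical_order

__all__ = [
    "SVMGrid",
    "REDUCED_GRID",
    "BinaryPLSDA",
    "BinarySVM",
    "OVOEnsemble",
    "pls_fit",
    "pls_predict",
    "select_plsda",
    "select_svm",
    "binary_probability",
    "ovo_train",
    "soft_vote",
    "predict",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class SVMGrid:
    """Log-spaced hyperparameter grid for the SVM search."""

    c_range: tuple[float, float] = (1e-3, 100.0)
    gamma_range: tuple[float, float] = (1e-6, 1e-1)
    c_points: int = 6
    gamma_points: int = 6

    def c_values(self) -> np.ndarray:
        return np.logspace(np.log10(self.c_range[0]), np.log10(self.c_range[1]), self.c_points)

    def gamma_values(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.gamma_range[0]), np.log10(self.gamma_range[1]), self.gamma_points
        )

    def candidates(self) -> list[tuple[str, float, float | None]]:
        """(kernel, C, gamma) in tie-preference order: linear first, then C, then gamma."""
        cands: list[tuple[str, float, float | None]] = [
            ("linear", float(c), None) for c in self.c_values()
        ]
        cands += [
            ("rbf", float(c), float(g))
            for c in self.c_values()
            for g in self.gamma_values()
        ]
        return cands


# Coarser grid for large leave-one-out experiments.
REDUCED_GRID = SVMGrid(c_points=3, gamma_points=3)


@dataclass
class BinaryPLSDA:
    """PLS regression on {0,1}-coded classes, used as a binary discriminant."""

    n_lv: int
    pls: PLSRegression
    classes: tuple = (0, 1)
    chain: PreprocessModel | None = None
    rmsecv: float | None = None
    cv_probabilities: np.ndarray | None = None


@dataclass
class BinarySVM:
    """Support-vector classifier with a logistic calibration of its margin."""

    kernel: str
    C: float
    gamma: float | None
    svc: SVC
    platt: tuple[float, float]
    classes: tuple = (0, 1)
    chain: PreprocessModel | None = None
    rmsecv: float | None = None
    cv_probabilities: np.ndarray | None = None


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> BinaryPLSDA:
    """Fit PLS regression of {0,1} response on X with ``n_lv`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds the rank {rank} of the training matrix")
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, y)
    return BinaryPLSDA(n_lv=n_lv, pls=pls)


def pls_predict(model: BinaryPLSDA, X: np.ndarray) -> np.ndarray:
    """Continuous PLS prediction (the fitted linear map applied to rows)."""
    return model.pls.predict(np.atleast_2d(np.asarray(X, dtype=float))).ravel()


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    lr = LogisticRegression(C=1.0, solver="lbfgs")
    lr.fit(decision.reshape(-1, 1), y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def binary_probability(model: BinaryPLSDA | BinarySVM, X: np.ndarray) -> np.ndarray:
    """P(class coded 1) for preprocessed rows X.

    PLS-DA: continuous prediction clipped to [0, 1].  SVM: logistic of
    the decision value with the training-fitted calibration, monotone
    in the margin.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(model, BinaryPLSDA):
        return np.clip(model.pls.predict(X).ravel(), 0.0, 1.0)
    a, b = model.platt
    return expit(a * model.svc.decision_function(X) + b)


def _loo_folds(X: np.ndarray, preprocess: bool) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-fold (train-transformed, test-transformed) pairs for leave-one-out.

    The preprocessing chain is refit on each fold's training rows; the
    MSC reference (training column mean of the absorbance matrix) is
    obtained by a rank-one downdate of the full sum.
    """
    n = len(X)
    idx = np.arange(n)
    if not preprocess:
        return [(X[idx != i], X[i][None, :]) for i in range(n)]
    A = log_inverse(X)
    total = A.sum(axis=0)
    folds = []
    for i in range(n):
        tr = idx != i
        ref = (total - A[i]) / (n - 1)
        Ztr = msc_apply(A[tr], ref)
        zte = msc_apply(A[i][None, :], ref)
        mu = Ztr.mean(axis=0)
        folds.append((Ztr - mu, zte - mu))
    return folds


def _loo_rmse(
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    y: np.ndarray,
    fit_predict,
) -> tuple[float, np.ndarray]:
    probs = np.empty(len(y), dtype=float)
    for i, (Ztr, zte) in enumerate(folds):
        ytr = np.delete(y, i)
        probs[i] = fit_predict(Ztr, ytr, zte)
    rmse = float(np.sqrt(np.mean((probs - y) ** 2)))
    return rmse, probs


def _fit_final_chain(X: np.ndarray, preprocess: bool) -> tuple[PreprocessModel | None, np.ndarray]:
    if not preprocess:
        return None, np.asarray(X, dtype=float)
    chain = preprocess_chain_fit(X)
    return chain, preprocess_chain_apply(X, chain)


def select_plsda(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 3,
    preprocess: bool = True,
) -> BinaryPLSDA:
    """Pick the LV count (1..3) minimizing LOO RMSEcv; ties prefer fewer LVs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, b = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out selection")
    folds = _loo_folds(X, preprocess)
    lv_cap = max(1, min(max_lv, n - 2, b))
    best: tuple[int, float, np.ndarray] | None = None
    for n_lv in range(1, lv_cap + 1):
        def fit_predict(Ztr, ytr, zte, n_lv=n_lv):
            pls = PLSRegression(n_components=n_lv, scale=False).fit(Ztr, ytr)
            return float(np.clip(pls.predict(zte).ravel()[0], 0.0, 1.0))

        rmse, probs = _loo_rmse(folds, y, fit_predict)
        if best is None or rmse < best[1] - 1e-12:
            best = (n_lv, rmse, probs)
    n_lv, rmse, probs = best
    chain, Z = _fit_final_chain(X, preprocess)
    pls = PLSRegression(n_components=n_lv, scale=False).fit(Z, y)
    return BinaryPLSDA(
        n_lv=n_lv, pls=pls, chain=chain, rmsecv=rmse, cv_probabilities=probs
    )


def select_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid: SVMGrid | None = None,
    preprocess: bool = True,
) -> BinarySVM:
    """Exhaustive grid search minimizing LOO RMSEcv on calibrated probabilities.

    Ties prefer the linear kernel, then smaller C, then smaller gamma
    (the candidate enumeration order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM selection needs both classes present")
    if len(X) < 3:
        raise ValueError("need at least 3 samples for leave-one-out selection")
    grid = grid or SVMGrid()
    folds = _loo_folds(X, preprocess)

    def make_fit_predict(kernel, C, gamma):
        def fit_predict(Ztr, ytr, zte):
            if len(np.unique(ytr)) < 2:
                return float(np.mean(ytr))
            svc = _make_svc(kernel, C, gamma).fit(Ztr, ytr)
            a, b = _platt_fit(svc.decision_function(Ztr), ytr)
            return float(expit(a * svc.decision_function(zte)[0] + b))

        return fit_predict

    best: tuple[tuple, float, np.ndarray] | None = None
    for kernel, C, gamma in grid.candidates():
        rmse, probs = _loo_rmse(folds, y, make_fit_predict(kernel, C, gamma))
        if best is None or rmse < best[1] - 1e-12:
            best = ((kernel, C, gamma), rmse, probs)
    (kernel, C, gamma), rmse, probs = best
    chain, Z = _fit_final_chain(X, preprocess)
    svc = _make_svc(kernel, C, gamma).fit(Z, y)
    platt = _platt_fit(svc.decision_function(Z), y)
    return BinarySVM(
        kernel=kernel,
        C=C,
        gamma=gamma,
        svc=svc,
        platt=platt,
        chain=chain,
        rmsecv=rmse,
        cv_probabilities=probs,
    )


def _make_svc(kernel: str, C: float, gamma: float | None) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    return SVC(kernel="rbf", C=C, gamma=gamma)


@dataclass
class OVOEnsemble:
    """One binary model per unordered class pair plus the soft-voting rule."""

    classes: list[str]
    models: dict[tuple[str, str], BinaryPLSDA | BinarySVM]
    learner: str
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.classes)
        if len(self.models) != k * (k - 1) // 2:
            raise ValueError("expected exactly K(K-1)/2 binary models")


def _select(learner: str, X, y, grid=None, max_lv: int = 3, preprocess: bool = True):
    if learner == "svm":
        return select_svm(X, y, grid=grid, preprocess=preprocess)
    if learner == "plsda":
        return select_plsda(X, y, max_lv=max_lv, preprocess=preprocess)
    raise ValueError(f"unknown learner family {learner!r}; expected 'svm' or 'plsda'")


def ovo_train(
    table: SpectraTable,
    learner: str = "svm",
    class_order: Sequence[str] | None = None,
    grid: SVMGrid | None = None,
    max_lv: int = 3,
) -> OVOEnsemble:
    """Train the one-vs-one ensemble: per pair, preprocess chain + selected learner.

    Within each pair the second class (later in canonical order) is
    coded 1; each stored model carries its own frozen preprocessing.
    """
    labels = table.meta["treatment"].to_numpy()
    order = list(class_order) if class_order is not None else canonical_order(np.unique(labels))
    for cls in order:
        if int((labels == cls).sum()) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    models: dict[tuple[str, str], BinaryPLSDA | BinarySVM] = {}
    for a, b in itertools.combinations(order, 2):
        mask = np.isin(labels, [a, b])
        y = (labels[mask] == b).astype(int)
        model = _select(learner, table.X[mask], y, grid=grid, max_lv=max_lv)
        model.classes = (a, b)
        models[(a, b)] = model
    return OVOEnsemble(
        classes=order,
        models=models,
        learner=learner,
        descriptor={"learner": learner, "classes": order, "n_pairs": len(models)},
    )


def soft_vote(
    pair_probabilities: Mapping[tuple[str, str], float],
    class_order: Sequence[str] | None = None,
) -> tuple[str, dict[str, float]]:
    """Average each class's probability over its binary models; argmax wins.

    ``pair_probabilities[(a, b)]`` is P(a) from the (a, b) binary model
    (so P(b) = 1 - P(a)).  Only the models involving a class enter its
    average.  Exact ties predict the earliest class in canonical order.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for (a, b), p_a in pair_probabilities.items():
        sums[a] = sums.get(a, 0.0) + p_a
        counts[a] = counts.get(a, 0) + 1
        sums[b] = sums.get(b, 0.0) + (1.0 - p_a)
        counts[b] = counts.get(b, 0) + 1
    averages = {c: sums[c] / counts[c] for c in sums}
    order = list(class_order) if class_order is not None else canonical_order(list(averages))
    order = [c for c in order if c in averages]
    winner = max(order, key=lambda c: (averages[c], -order.index(c)))
    return winner, averages


def _pair_probability_matrix(ensemble: OVOEnsemble, X: np.ndarray) -> dict:
    """P(second class) from every pair model for every row (chain applied per pair)."""
    out = {}
    for pair, model in ensemble.models.items():
        Z = preprocess_chain_apply(X, model.chain) if model.chain is not None else X
        out[pair] = binary_probability(model, Z)
    return out


def predict(
    ensemble: OVOEnsemble, data: SpectraTable | np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    """Soft-vote predictions and the per-class average-probability table."""
    X = data.X if isinstance(data, SpectraTable) else np.atleast_2d(np.asarray(data, float))
    pair_probs = _pair_probability_matrix(ensemble, X)
    order = ensemble.classes
    k = len(order)
    col = {c: i for i, c in enumerate(order)}
    sums = np.zeros((X.shape[0], k))
    for (a, b), p_b in pair_probs.items():
        sums[:, col[a]] += 1.0 - p_b
        sums[:, col[b]] += p_b
    averages = sums / (k - 1)
    winners = np.array([order[i] for i in np.argmax(averages, axis=1)])
    return winners, pd.DataFrame(averages, columns=order)


class _LinearPLSPredictor:
    """Frozen PLS regression map rebuilt from its arrays (duck-types .predict)."""

    def __init__(self, coef: np.ndarray, x_mean: np.ndarray, intercept: np.ndarray):
        self.coef = coef
        self.x_mean = x_mean
        self.intercept = intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) @ self.coef.T + self.intercept


class _SVMDecision:
    """Frozen SVM decision function rebuilt from support vectors and dual coefs."""

    def __init__(self, kernel, gamma, support_vectors, dual_coef, intercept):
        self.kernel = kernel
        self.gamma = gamma
        self.support_vectors = support_vectors
        self.dual_coef = dual_coef
        self.intercept = intercept

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.kernel == "linear":
            K = X @ self.support_vectors.T
        else:
            sq = (
                (X**2).sum(axis=1)[:, None]
                + (self.support_vectors**2).sum(axis=1)[None, :]
                - 2.0 * X @ self.support_vectors.T
            )
            K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef.ravel() + self.intercept


def save_ensemble(ensemble: OVOEnsemble, path: str) -> None:
    """Serialize an ensemble as a directory: JSON descriptor + array payloads."""
    os.makedirs(path, exist_ok=True)
    pairs = []
    arrays: dict[str, np.ndarray] = {}
    for i, ((a, b), model) in enumerate(sorted(ensemble.models.items())):
        key = f"pair{i:03d}"
        entry: dict = {"classes": [a, b], "key": key}
        if model.chain is not None:
            arrays[f"{key}_msc_reference"] = model.chain.msc_reference
            arrays[f"{key}_column_means"] = model.chain.column_means
            entry["log_floor"] = model.chain.log_floor
        if isinstance(model, BinaryPLSDA):
            entry.update(kind="plsda", n_lv=model.n_lv, rmsecv=model.rmsecv)
            arrays[f"{key}_coef"] = np.asarray(model.pls.coef_)
            arrays[f"{key}_x_mean"] = np.asarray(model.pls._x_mean)
            arrays[f"{key}_intercept"] = np.asarray(model.pls.intercept_)
        else:
            entry.update(
                kind="svm", kernel=model.kernel, C=model.C, gamma=model.gamma,
                platt=list(model.platt), rmsecv=model.rmsecv,
                intercept=float(model.svc.intercept_[0]),
            )
            arrays[f"{key}_support_vectors"] = model.svc.support_vectors_
            arrays[f"{key}_dual_coef"] = model.svc.dual_coef_
        pairs.append(entry)
    with open(os.path.join(path, "descriptor.json"), "w") as fh:
        json.dump(
            {"learner": ensemble.learner, "classes": ensemble.classes,
             "descriptor": ensemble.descriptor, "pairs": pairs},
            fh, indent=2,
        )
    np.savez(os.path.join(path, "arrays.npz"), **arrays)


def load_ensemble(path: str) -> OVOEnsemble:
    """Rebuild a saved ensemble; predictions match the original exactly."""
    with open(os.path.join(path, "descriptor.json")) as fh:
        desc = json.load(fh)
    arrays = np.load(os.path.join(path, "arrays.npz"))
    models: dict[tuple[str, str], BinaryPLSDA | BinarySVM] = {}
    for entry in desc["pairs"]:
        key = entry["key"]
        a, b = entry["classes"]
        chain = None
        if f"{key}_msc_reference" in arrays:
            chain = PreprocessModel(
                msc_reference=arrays[f"{key}_msc_reference"],
                column_means=arrays[f"{key}_column_means"],
                log_floor=entry.get("log_floor", 1e-4),
            )
        if entry["kind"] == "plsda":
            pls = _LinearPLSPredictor(
                coef=arrays[f"{key}_coef"],
                x_mean=arrays[f"{key}_x_mean"],
                intercept=arrays[f"{key}_intercept"],
            )
            model: BinaryPLSDA | BinarySVM = BinaryPLSDA(
                n_lv=entry["n_lv"], pls=pls, classes=(a, b), chain=chain,
                rmsecv=entry.get("rmsecv"),
            )
        else:
            svc = _SVMDecision(
                kernel=entry["kernel"], gamma=entry["gamma"],
                support_vectors=arrays[f"{key}_support_vectors"],
                dual_coef=arrays[f"{key}_dual_coef"],
                intercept=entry["intercept"],
            )
            model = BinarySVM(
                kernel=entry["kernel"], C=entry["C"], gamma=entry["gamma"],
                svc=svc, platt=tuple(entry["platt"]), classes=(a, b),
                chain=chain, rmsecv=entry.get("rmsecv"),
            )
        models[(a, b)] = model
    return OVOEnsemble(
        classes=list(desc["classes"]), models=models,
        learner=desc["learner"], descriptor=desc.get("descriptor", {}),
    )
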