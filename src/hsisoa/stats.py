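"""Exploratory statistics: NDVI with pairwise t-tests, and Random-Forest band importance.

NDVI = (R_nir - R_red) / (R_nir + R_red) summarizes chlorophyll
activity in one number; Welch two-sample t-tests over every unordered
pair of treatment groups show which herbicide stresses NDVI alone can
already separate.  Random-Forest impurity importance over the full
spectrum (100 trees, seed 42) ranks wavelengths by discriminative
power, either one class against the rest or restricted to a class
pair; the per-pair top bands form the band-importance heatmap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .preprocess import SpectraTable
from .segmentation import SpectrumRecord, _nearest_index
from .synthetic import canonical_order

__all__ = [
    "PValueMatrix",
    "BandImportanceResult",
    "ndvi",
    "pairwise_ttest",
    "band_importance",
    "pairwise_top_bands",
    "importance_heatmap",
    "plot_pvalue_heatmap",
]


@dataclass
class PValueMatrix:
    """Symmetric K x K matrix of two-sided p-values (diagonal NaN)."""

    pvalues: np.ndarray
    classes: list[str]
    test: str = "welch-t two-sided"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.classes, columns=self.classes)


@dataclass
class BandImportanceResult:
    """Normalized band importances for one binary comparison."""

    comparison: tuple
    importances: np.ndarray
    wavelengths: np.ndarray
    top_band_nm: float
    settings: dict = field(default_factory=lambda: {"n_estimators": 100, "random_state": 42})


def ndvi(
    record: SpectrumRecord | tuple[np.ndarray, np.ndarray],
    red_nm: float = 670.0,
    nir_nm: float = 800.0,
) -> float:
    """Normalized difference vegetation index from the nearest red/NIR bands."""
    if isinstance(record, SpectrumRecord):
        values, wl = record.values, record.wavelengths
    else:
        values, wl = np.asarray(record[0], float), np.asarray(record[1], float)
    red = values[_nearest_index(wl, red_nm)]
    nir = values[_nearest_index(wl, nir_nm)]
    total = nir + red
    if total == 0:
        raise ValueError("NDVI undefined: R_nir + R_red = 0")
    return float((nir - red) / total)


def ndvi_table(table: SpectraTable, red_nm: float = 670.0, nir_nm: float = 800.0) -> pd.Series:
    """NDVI per row of a spectra table."""
    red = table.X[:, _nearest_index(table.wavelengths, red_nm)]
    nir = table.X[:, _nearest_index(table.wavelengths, nir_nm)]
    return pd.Series((nir - red) / (nir + red), index=table.meta.index, name="ndvi")


def pairwise_ttest(values_by_class: Mapping[str, np.ndarray]) -> PValueMatrix:
    """Welch two-sided t-test for every unordered pair of independent groups.

    Groups with fewer than 2 samples get NaN rows/columns with a warning.
    """
    classes = canonical_order(list(values_by_class))
    k = len(classes)
    p = np.full((k, k), np.nan)
    usable = {}
    for name in classes:
        vals = np.asarray(values_by_class[name], dtype=float)
        if vals.size < 2:
            warnings.warn(f"class {name!r} has < 2 samples; p-values undefined")
        else:
            usable[name] = vals
    for i in range(k):
        for j in range(i + 1, k):
            a, b = classes[i], classes[j]
            if a in usable and b in usable:
                res = sps.ttest_ind(usable[a], usable[b], equal_var=False)
                p[i, j] = p[j, i] = res.pvalue
    return PValueMatrix(pvalues=p, classes=classes)


def holm_adjust(matrix: PValueMatrix) -> PValueMatrix:
    """Holm step-down adjustment over the upper-triangle p-values."""
    p = matrix.pvalues.copy()
    iu = np.triu_indices_from(p, k=1)
    raw = p[iu]
    ok = ~np.isnan(raw)
    m = int(ok.sum())
    order = np.argsort(raw[ok])
    adj = np.minimum.accumulate(((m - np.arange(m)) * raw[ok][order])[::-1])[::-1]
    adjusted = np.full_like(raw, np.nan)
    adjusted[np.flatnonzero(ok)[order]] = np.clip(adj, 0, 1)
    p[iu] = adjusted
    p[(iu[1], iu[0])] = adjusted
    return PValueMatrix(pvalues=p, classes=list(matrix.classes), test=matrix.test + " holm")


def band_importance(
    table: SpectraTable,
    comparison: tuple,
    n_estimators: int = 100,
    random_state: int = 42,
) -> BandImportanceResult:
    """Impurity-based Random-Forest band importance for a binary comparison.

    ``comparison`` is ``("one_vs_rest", cls)`` (that class against all
    other rows) or ``("pair", a, b)`` (rows restricted to the two
    classes).  Importances are normalized to sum to 1; the top band is
    the argmax wavelength.
    """
    labels = table.meta["treatment"].to_numpy()
    if comparison[0] == "one_vs_rest":
        target = comparison[1]
        X = table.X
        y = (labels == target).astype(int)
    elif comparison[0] == "pair":
        a, b = comparison[1], comparison[2]
        keep = np.isin(labels, [a, b])
        X = table.X[keep]
        y = (labels[keep] == b).astype(int)
    else:
        raise ValueError(f"unknown comparison mode {comparison[0]!r}")
    if len(np.unique(y)) < 2:
        raise ValueError(f"comparison {comparison} yields a single class")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=random_state, n_jobs=1
    )
    forest.fit(X, y)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    top = float(table.wavelengths[int(np.argmax(imp))])
    return BandImportanceResult(
        comparison=tuple(comparison),
        importances=imp,
        wavelengths=table.wavelengths.copy(),
        top_band_nm=top,
        settings={"n_estimators": n_estimators, "random_state": random_state},
    )


def pairwise_top_bands(
    table: SpectraTable,
    classes: Sequence[str] | None = None,
    n_estimators: int = 100,
    random_state: int = 42,
) -> list[BandImportanceResult]:
    """Band importance for every unordered class pair present in the table."""
    if classes is None:
        classes = canonical_order(table.meta["treatment"].unique().tolist())
    results = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            results.append(
                band_importance(table, ("pair", a, b), n_estimators, random_state)
            )
    return results


def importance_heatmap(results: Sequence[BandImportanceResult]) -> pd.DataFrame:
    """Symmetric K x K matrix of per-pair top-band wavelengths (nm); diagonal NaN."""
    pairs = [r.comparison for r in results]
    if any(p[0] != "pair" for p in pairs):
        raise ValueError("importance_heatmap requires pair-mode results")
    classes = canonical_order(sorted({c for p in pairs for c in p[1:]}))
    mat = pd.DataFrame(np.nan, index=classes, columns=classes)
    for r in results:
        _, a, b = r.comparison
        mat.loc[a, b] = mat.loc[b, a] = r.top_band_nm
    return mat


def plot_pvalue_heatmap(matrix: PValueMatrix | pd.DataFrame, path: str, title: str = "") -> None:
    """Render an annotated heatmap to ``path`` (works for p-values or top bands)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    frame = matrix.to_frame() if isinstance(matrix, PValueMatrix) else matrix
    fig, ax = plt.subplots(figsize=(1.1 * len(frame) + 2, 1.0 * len(frame) + 1.5))
    sns.heatmap(frame, annot=True, fmt=".2f", cmap="coolwarm", ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
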