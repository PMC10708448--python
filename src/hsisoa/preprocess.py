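"""Chemometric spectral preprocessing with train-fit / test-apply discipline.

Extraction-time smoothing uses a Savitzky-Golay filter (order 1,
window 5).  The model-side chain, applied in this order, is

    log10(1/R)  ->  multiplicative scatter correction (MSC)  ->  mean centering

MSC regresses each absorbance spectrum x on a reference spectrum
(the training-set column mean), x ~ a + b*ref, and returns (x - a)/b,
removing per-sample additive offset and multiplicative gain.  All three
steps are fitted on training rows only and frozen into a
:class:`PreprocessModel` so held-out or later-day spectra are
transformed without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraTable",
    "PreprocessModel",
    "savgol_smooth",
    "log_inverse",
    "msc_fit",
    "msc_apply",
    "mean_center_fit",
    "mean_center_apply",
    "preprocess_chain_fit",
    "preprocess_chain_apply",
]

META_COLUMNS = ["sample_id", "treatment", "soa", "moa_group", "dat", "round", "outlier"]


@dataclass
class SpectraTable:
    """Samples-by-bands matrix with per-row labels; the modelling dataset.

    ``meta`` columns: sample_id, treatment, soa, moa_group, dat, round,
    outlier.  A (sample_id, dat, round) triple is unique.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError("column count must equal wavelength count")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta rows must match X rows")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns {missing}")
        key = self.meta[["sample_id", "dat", "round"]]
        if key.duplicated().any():
            raise ValueError("duplicated (sample_id, dat, round) rows in meta")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    def select(self, mask: np.ndarray) -> "SpectraTable":
        mask = np.asarray(mask)
        return SpectraTable(
            X=self.X[mask],
            wavelengths=self.wavelengths,
            meta=self.meta.loc[mask].reset_index(drop=True),
        )

    def filter(
        self,
        dat: int | Iterable[int] | None = None,
        rounds: int | Iterable[int] | None = None,
        treatments: Sequence[str] | None = None,
        drop_outliers: bool = False,
    ) -> "SpectraTable":
        """Row subset by day(s) after treatment, round(s) and treatment labels."""
        keep = np.ones(len(self), dtype=bool)
        if dat is not None:
            dats = [dat] if np.isscalar(dat) else list(dat)
            keep &= self.meta["dat"].isin(dats).to_numpy()
        if rounds is not None:
            rs = [rounds] if np.isscalar(rounds) else list(rounds)
            keep &= self.meta["round"].isin(rs).to_numpy()
        if treatments is not None:
            keep &= self.meta["treatment"].isin(list(treatments)).to_numpy()
        if drop_outliers:
            keep &= ~self.meta["outlier"].to_numpy().astype(bool)
        return self.select(keep)

    def to_csv(self, path: str) -> None:
        """Interchange CSV: metadata columns then one column per wavelength (nm)."""
        df = self.meta.copy()
        spec = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths])
        pd.concat([df, spec], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SpectraTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c not in META_COLUMNS]
        wavelengths = np.array([float(c) for c in wl_cols])
        return cls(
            X=df[wl_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
            meta=df[META_COLUMNS].copy(),
        )


def savgol_smooth(spectrum: np.ndarray, window: int = 5, order: int = 1) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing along the last axis.

    For order 1 the interior equals the ``window``-point moving average;
    edges come from a polynomial fit over the one-sided end window
    rather than from padded, invented reflectance.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("polynomial order must be smaller than the window")
    if spectrum.shape[-1] < window:
        raise ValueError(
            f"spectrum of length {spectrum.shape[-1]} is shorter than window {window}"
        )
    return savgol_filter(spectrum, window_length=window, polyorder=order, mode="interp", axis=-1)


def log_inverse(spectrum: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Pseudo-absorbance log10(1/R); reflectance below ``floor`` is floored with a warning."""
    spectrum = np.asarray(spectrum, dtype=float)
    if np.any(spectrum < floor):
        warnings.warn(
            f"reflectance values <= {floor:g} floored before log(1/R)", stacklevel=2
        )
        spectrum = np.maximum(spectrum, floor)
    return np.log10(1.0 / spectrum)


def msc_fit(X_train: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the column mean of the training matrix."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("MSC needs at least 2 training spectra")
    ref = X_train.mean(axis=0)
    if not np.all(np.isfinite(ref)) or np.ptp(ref) == 0:
        raise ValueError("MSC reference must be finite and non-constant")
    return ref


def msc_apply(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Correct spectra against the reference: fit x ~ a + b*ref (OLS), return (x - a)/b."""
    arr = np.asarray(x, dtype=float)
    one_d = arr.ndim == 1
    X = np.atleast_2d(arr)
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("degenerate spectrum: MSC slope |b| < 1e-12")
    a = X.mean(axis=1) - b * ref.mean()
    corrected = (X - a[:, None]) / b[:, None]
    return corrected[0] if one_d else corrected


def mean_center_fit(X_train: np.ndarray) -> np.ndarray:
    """Column means of the training matrix."""
    return np.asarray(X_train, dtype=float).mean(axis=0)


def mean_center_apply(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) - np.asarray(means, dtype=float)


@dataclass
class PreprocessModel:
    """Frozen parameters of the log(1/R) -> MSC -> mean-centering chain."""

    msc_reference: np.ndarray
    column_means: np.ndarray
    chain: tuple[str, ...] = ("log_inverse", "msc", "mean_center")
    log_floor: float = 1e-4
    descriptor: dict = field(default_factory=dict)


def preprocess_chain_fit(X_train: np.ndarray, log_floor: float = 1e-4) -> PreprocessModel:
    """Fit the chain on training rows only and freeze its parameters."""
    A = log_inverse(X_train, floor=log_floor)
    ref = msc_fit(A)
    corrected = msc_apply(A, ref)
    means = mean_center_fit(corrected)
    return PreprocessModel(msc_reference=ref, column_means=means, log_floor=log_floor)


def preprocess_chain_apply(X: np.ndarray, model: PreprocessModel) -> np.ndarray:
    """Transform rows with fitted parameters only (no refitting)."""
    A = log_inverse(X, floor=model.log_floor)
    corrected = np.atleast_2d(msc_apply(A, model.msc_reference))
    out = mean_center_apply(corrected, model.column_means)
    return out[0] if np.asarray(X).ndim == 1 else out
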