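"""Red-edge slope segmentation and mean-spectrum extraction.

Vegetation reflectance rises steeply between ~680 and ~732 nm (the red
edge) while a flat bright background does not.  Convolving each pixel's
spectrum over that window with a centered integer ramp ``lin = -m..m``
and normalising by ``lin . lin`` yields the least-squares slope of the
spectrum per band step:

    con[p] = sum_k lin_k * x[p, k] / sum_k lin_k**2

Plant pixels are those whose slope exceeds a threshold (default 7 on
the ten-thousandths reflectance scale); the mean spectrum over plant
pixels, cropped to the high-SNR 460-975 nm range, is the sample's
modelling input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io import HyperCube

__all__ = [
    "SCALE_FACTORS",
    "RedEdgeWindow",
    "PlantMask",
    "SpectrumRecord",
    "make_window",
    "rededge_slope_map",
    "segment",
    "crop_indices",
    "mean_spectrum",
]

# Numeric conventions for reflectance.  The slope threshold is
# scale-covariant, so the scale the threshold refers to must be named
# explicitly.  A realistic red edge has slope ~0.007 reflectance
# fraction per 1.2 nm band, i.e. ~70 on the ten-thousandths scale --
# comfortably above the default threshold of 7 -- whereas on the
# percent scale the same edge has slope ~0.7 and the largest slope any
# [0, 100]-bounded spectrum can achieve over a 43-band window is ~3.5.
SCALE_FACTORS = {"fraction": 1.0, "percent": 100.0, "tenthousandths": 10000.0}


@dataclass
class RedEdgeWindow:
    """Inclusive band-index window plus its centered integer ramp."""

    start: int
    stop: int  # inclusive
    ramp: np.ndarray

    def __post_init__(self) -> None:
        self.ramp = np.asarray(self.ramp)
        n = self.stop - self.start + 1
        if self.ramp.size != n:
            raise ValueError("ramp length must equal window length")
        if n % 2 == 0 or n < 3:
            raise ValueError("window must have odd length >= 3")
        m = (n - 1) // 2
        if not np.array_equal(self.ramp, np.arange(-m, m + 1)):
            raise ValueError("ramp must be the symmetric integer ramp -m..m")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)

    def __len__(self) -> int:
        return self.stop - self.start + 1


@dataclass
class PlantMask:
    """Boolean plant-pixel mask with the threshold and window that produced it."""

    mask: np.ndarray
    threshold: float
    window: RedEdgeWindow | None = None
    scale: str = "tenthousandths"

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpectrumRecord:
    """Mean plant spectrum on the cropped grid, with provenance metadata."""

    values: np.ndarray
    wavelengths: np.ndarray
    pixel_count: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError("values and wavelengths must have equal length")
        if self.pixel_count < 1:
            raise ValueError("pixel count must be >= 1")


def _nearest_index(wavelengths: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(np.asarray(wavelengths) - target)))


def make_window(wavelengths: np.ndarray, lo: float = 680.0, hi: float = 732.0) -> RedEdgeWindow:
    """Build the red-edge window over bands nearest [lo, hi] and its ramp.

    If the nearest-band window has even length it is trimmed by one band
    from the high-wavelength end so that a symmetric zero-sum ramp
    exists.  On a grid where [680, 732] nm holds 41 bands the ramp is
    the classic -20..20 vector.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength grid")
    if wavelengths[0] > lo or wavelengths[-1] < hi:
        raise ValueError(
            f"grid [{wavelengths[0]:.1f}, {wavelengths[-1]:.1f}] nm does not cover "
            f"the window [{lo:.1f}, {hi:.1f}] nm"
        )
    start = _nearest_index(wavelengths, lo)
    stop = _nearest_index(wavelengths, hi)
    n = stop - start + 1
    if n % 2 == 0:
        stop -= 1
        n -= 1
    if n < 3:
        raise ValueError(f"red-edge window holds only {n} bands; need at least 3")
    m = (n - 1) // 2
    return RedEdgeWindow(start=start, stop=stop, ramp=np.arange(-m, m + 1))


def rededge_slope_map(cube: HyperCube, window: RedEdgeWindow) -> np.ndarray:
    """Per-pixel least-squares red-edge slope (per band step) over the window."""
    if cube.kind != "reflectance":
        raise ValueError("slope map requires a calibrated reflectance cube")
    if window.stop >= cube.n_bands:
        raise ValueError("window indices exceed cube band count")
    x = cube.data[:, :, window.start : window.stop + 1]
    if np.isnan(x).any():
        warnings.warn("NaN values inside the red-edge window; slope NaN propagated")
    ramp = window.ramp.astype(float)
    return np.tensordot(x, ramp, axes=([2], [0])) / float(ramp @ ramp)


def segment(
    cube: HyperCube,
    window: RedEdgeWindow | None = None,
    threshold: float = 7.0,
    scale: str = "tenthousandths",
) -> PlantMask:
    """Threshold the red-edge slope map into a plant mask (strict ``con > threshold``).

    No morphological post-processing is applied.  ``scale`` names the
    reflectance convention the threshold refers to; the slope map is
    multiplied by the corresponding factor before comparison.
    """
    if scale not in SCALE_FACTORS:
        raise ValueError(f"unknown reflectance scale {scale!r}")
    if window is None:
        window = make_window(cube.wavelengths)
    con = rededge_slope_map(cube, window) * SCALE_FACTORS[scale]
    return PlantMask(mask=con > threshold, threshold=threshold, window=window, scale=scale)


def crop_indices(wavelengths: np.ndarray, lo: float = 460.0, hi: float = 975.0) -> np.ndarray:
    """Band indices for the inclusive nearest-band crop [lo, hi] nm."""
    start = _nearest_index(wavelengths, lo)
    stop = _nearest_index(wavelengths, hi)
    if stop < start:
        raise ValueError("crop range is empty on this grid")
    return np.arange(start, stop + 1)


def mean_spectrum(
    cube: HyperCube,
    mask: PlantMask | np.ndarray,
    crop: tuple[float, float] | None = (460.0, 975.0),
) -> SpectrumRecord:
    """Arithmetic mean spectrum over masked pixels, cropped to ``crop`` nm.

    Raises if the mask is empty -- callers drop such samples, the same
    way plants the imaging system failed to capture are dropped.
    """
    m = mask.mask if isinstance(mask, PlantMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    count = int(m.sum())
    if count == 0:
        raise ValueError("no plant pixels: empty segmentation mask")
    spectrum = cube.data[m].mean(axis=0)
    wavelengths = cube.wavelengths
    if crop is not None:
        idx = crop_indices(wavelengths, *crop)
        spectrum = spectrum[idx]
        wavelengths = wavelengths[idx]
    return SpectrumRecord(
        values=spectrum,
        wavelengths=wavelengths.copy(),
        pixel_count=count,
        meta=dict(cube.meta),
    )
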