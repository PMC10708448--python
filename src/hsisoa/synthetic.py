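"""Synthetic hyperspectral scenes and study-shaped datasets with known truth.

The study data this pipeline targets (barnyard grass imaged daily for a
week after treatment with 8 herbicides spanning 4 mode-of-action
groups) are not public, so every downstream stage is exercised on
synthetic data instead: a parametric leaf endmember with a steep red
edge, class-specific Gaussian spectral perturbations whose severity
grows with days after treatment (DAT), saturating damage that makes
all treated plants converge toward a common chlorotic spectrum on
later days, line-scan scene rendering with dark/white reference
frames, and sensor noise.

The generator's defaults mirror the study design: 9 classes (untreated
control + 8 herbicides), 16 samples per herbicide and 32 controls per
round, 2 rounds (320 samples), 7 daily time points, 5 outlier plants
severely damaged on 2 DAT, and a 380-1030 nm grid at 1.2 nm steps.

All stochasticity flows from one root seed through
``numpy.random.SeedSequence`` spawning (one stream per sample for
biology, one per sample-day for measurement), so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .io import HyperCube, ReferenceFrames
from .preprocess import SpectraTable, savgol_smooth
from .segmentation import crop_indices

__all__ = [
    "CONTROL",
    "CANONICAL_ORDER",
    "EffectBand",
    "TreatmentSpec",
    "SceneConfig",
    "StudyConfig",
    "Scene",
    "StudyData",
    "default_treatments",
    "canonical_order",
    "leaf_endmember",
    "apply_treatment_effect",
    "render_scene",
    "generate_study",
]

CONTROL = "UTC"

# Treatment vocabulary: herbicide -> (MOA group, SOA target, dose g/ha).
_TREATMENT_TABLE: dict[str, tuple[str, str, float]] = {
    "Atrazine": ("Photosynthesis inhibition", "PS II inhibition", 62.5),
    "Dinoseb": ("Photosynthesis inhibition", "Uncoupler", 125.0),
    "Flumioxazin": ("Cell membrane disrupter", "PPO enzyme", 1.56),
    "Paraquat": ("Cell membrane disrupter", "PS I electron diversion", 3.9),
    "Glyphosate": ("Amino acid synthesis inhibition", "EPSPS synthase", 15.6),
    "Glufosinate": ("Amino acid synthesis inhibition", "Glutamine synthase", 62.5),
    "Chlorimuron": ("Amino acid synthesis inhibition", "ALS enzyme", 25.0),
    "Indaziflam": ("Cellulose biosynthesis inhibitor", "Cellulose synthesis", 62.5),
}

CANONICAL_ORDER = [CONTROL] + list(_TREATMENT_TABLE)


def canonical_order(labels: Sequence[str]) -> list[str]:
    """Order class labels canonically: control first, then herbicide table order."""
    present = set(labels)
    ordered = [c for c in CANONICAL_ORDER if c in present]
    ordered += sorted(present - set(CANONICAL_ORDER))
    return ordered


@dataclass(frozen=True)
class EffectBand:
    """A localized Gaussian perturbation of leaf reflectance.

    ``amplitude`` is multiplicative at the band center (0.2 = +20%
    reflectance); negative amplitudes are absorptions/losses.  The band
    is inactive before ``onset_day``.
    """

    center_nm: float
    width_nm: float
    amplitude: float
    onset_day: int = 0


@dataclass
class TreatmentSpec:
    """One treatment class: labels, dose metadata and its spectral signature."""

    name: str
    moa_group: str
    soa_target: str
    dose_g_ha: float
    effect_bands: tuple[EffectBand, ...] = ()
    severity_growth: float = 1.25
    stress_rate: float = 0.0

    def __post_init__(self) -> None:
        for band in self.effect_bands:
            if not np.isfinite(band.amplitude):
                raise ValueError(f"non-finite amplitude in {self.name}")
        if self.name == CONTROL and self.effect_bands:
            raise ValueError("untreated control must have no effect bands")
        if self.stress_rate < 0:
            raise ValueError("stress rate must be >= 0")


# Class-specific signatures: distinct primary centers spread over the
# 533-923 nm range where herbicide-discriminative bands are found.
_EFFECTS: dict[str, tuple[EffectBand, ...]] = {
    "Atrazine": (EffectBand(700.0, 12.0, +0.22), EffectBand(545.0, 20.0, +0.10)),
    "Dinoseb": (EffectBand(920.0, 30.0, -0.18), EffectBand(680.0, 10.0, +0.12)),
    "Flumioxazin": (EffectBand(533.0, 14.0, +0.20), EffectBand(640.0, 12.0, +0.10)),
    "Paraquat": (EffectBand(860.0, 28.0, -0.20), EffectBand(740.0, 15.0, -0.10)),
    "Glyphosate": (EffectBand(580.0, 12.0, +0.12), EffectBand(705.0, 10.0, +0.07)),
    "Glufosinate": (EffectBand(585.0, 12.0, -0.12), EffectBand(765.0, 18.0, -0.10)),
    "Chlorimuron": (EffectBand(600.0, 14.0, +0.14), EffectBand(688.0, 8.0, +0.08)),
    "Indaziflam": (EffectBand(640.0, 14.0, -0.14), EffectBand(800.0, 30.0, -0.12)),
}

# Temporal dynamics: (per-day severity multiplier, per-day damage
# accumulation rate).  Contact herbicides (paraquat, dinoseb) damage
# tissue fast; the paraquat-specific signal fades as days progress,
# while photosynthesis-inhibitor signatures strengthen; systemic
# amino-acid and cellulose inhibitors progress slowly.
_DYNAMICS: dict[str, tuple[float, float]] = {
    "Atrazine": (1.25, 0.15),
    "Dinoseb": (1.10, 0.25),
    "Flumioxazin": (1.15, 0.15),
    "Paraquat": (0.45, 0.25),
    "Glyphosate": (0.60, 0.08),
    "Glufosinate": (1.10, 0.15),
    "Chlorimuron": (1.15, 0.08),
    "Indaziflam": (1.20, 0.08),
}


def default_treatments(amplitude_scale: float = 1.0) -> list[TreatmentSpec]:
    """The 9 study classes with their default synthetic spectral signatures.

    Effect bands are anchored at 1 DAT (onset day 1): the listed
    amplitude is the day-1 magnitude and evolves as
    ``severity_growth**(day - 1)`` afterwards.
    """
    specs = [TreatmentSpec(CONTROL, "control", "untreated", 0.0, ())]
    for name, (moa, soa, dose) in _TREATMENT_TABLE.items():
        bands = tuple(
            EffectBand(b.center_nm, b.width_nm, b.amplitude * amplitude_scale, onset_day=1)
            for b in _EFFECTS[name]
        )
        growth, rate = _DYNAMICS[name]
        specs.append(
            TreatmentSpec(
                name, moa, soa, dose, bands, severity_growth=growth, stress_rate=rate
            )
        )
    return specs


def leaf_endmember(
    wavelengths: np.ndarray,
    *,
    nir_plateau: float = 0.55,
    red_edge_center: float = 705.0,
    red_edge_width: float = 14.0,
    base: float = 0.05,
    green_amp: float = 0.07,
    chl_red_depth: float = 0.025,
    chl_blue_depth: float = 0.02,
    water_depth: float = 0.05,
) -> np.ndarray:
    """Parametric healthy-vegetation reflectance on ``wavelengths`` (nm).

    Green bump at 550 nm, chlorophyll absorption wells in the blue and
    red, a sigmoidal red edge near 705 nm rising to an NIR plateau, and
    a 970 nm water feature.  Values lie in (0, 1); the red-edge slope
    between 680 and 732 nm is strictly positive by construction.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be monotone increasing")
    r = (
        base
        + green_amp * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
        + (nir_plateau - base) * expit((wl - red_edge_center) / red_edge_width)
        - chl_red_depth * np.exp(-0.5 * ((wl - 670.0) / 18.0) ** 2)
        - chl_blue_depth * np.exp(-0.5 * ((wl - 450.0) / 25.0) ** 2)
        - water_depth * np.exp(-0.5 * ((wl - 970.0) / 22.0) ** 2)
    )
    return np.clip(r, 0.005, 0.995)


def damaged_endmember(wavelengths: np.ndarray) -> np.ndarray:
    """Reflectance of severely stressed (chlorotic, desiccating) leaf tissue.

    Collapsed NIR plateau, flattened and blue-shifted red edge, weak
    chlorophyll absorption -- the common spectrum herbicide-damaged
    plants converge to regardless of the site of action.
    """
    return leaf_endmember(
        wavelengths,
        nir_plateau=0.35,
        red_edge_center=695.0,
        red_edge_width=22.0,
        base=0.09,
        green_amp=0.05,
        chl_red_depth=0.005,
        chl_blue_depth=0.005,
        water_depth=0.02,
    )


def damage_weight(spec: TreatmentSpec, day: int, severity_scale: float = 1.0) -> float:
    """Fraction of the common damaged-leaf spectrum mixed in at ``day``.

    Damage accumulates from the day after the first acquisition,
    saturating as ``1 - exp(-stress_rate * severity * (day - 1))``; it
    is zero on day 1 (and always zero for the untreated control).  This
    between-day convergence of all treated classes toward one damaged
    spectrum is what degrades a model trained on one day and tested on
    another.
    """
    if spec.stress_rate <= 0 or day <= 1:
        return 0.0
    return float(1.0 - np.exp(-spec.stress_rate * severity_scale * (day - 1)))


def apply_treatment_effect(
    base: np.ndarray,
    wavelengths: np.ndarray,
    spec: TreatmentSpec,
    day: int,
    severity_scale: float = 1.0,
) -> np.ndarray:
    """Deterministically perturb a spectrum with the treatment's active bands.

    Each band active at ``day`` (``onset_day <= day``) multiplies
    reflectance by ``1 + amplitude * severity_growth**(day - onset_day)
    * gaussian(center, width)``; the result is clipped to (0, 1).
    The control (no bands) returns ``base`` unchanged.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    wl = np.asarray(wavelengths, dtype=float)
    out = np.asarray(base, dtype=float).copy()
    for band in spec.effect_bands:
        if day < band.onset_day:
            continue
        magnitude = (
            band.amplitude
            * severity_scale
            * spec.severity_growth ** (day - band.onset_day)
        )
        shape = np.exp(-0.5 * ((wl - band.center_nm) / band.width_nm) ** 2)
        out = out * (1.0 + magnitude * shape)
    return np.clip(out, 1e-6, 1.0 - 1e-6)


@dataclass
class SceneConfig:
    """Geometry, optics and noise of one rendered line-scan scene."""

    height: int = 96
    width: int = 128
    wl_start: float = 380.0
    wl_stop: float = 1030.0
    wl_step: float = 1.2
    plant_fraction: float = 0.25
    background_reflectance: float = 0.95
    illum_amplitude: float = 0.08
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_step <= 0:
            raise ValueError("wavelength step must be > 0")
        if self.wl_stop <= self.wl_start:
            raise ValueError("wavelength stop must exceed start")
        if not 0.0 <= self.plant_fraction < 1.0:
            raise ValueError("plant fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop, self.wl_step)


@dataclass
class Scene:
    """A rendered raw cube with its reference frames and ground-truth mask."""

    raw: HyperCube
    refs: ReferenceFrames
    truth_mask: np.ndarray


def _plant_silhouette(height: int, width: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Connected plant-shaped blob (body, stem, leaf lobes) covering ~fraction of the frame."""
    mask = np.zeros((height, width), dtype=bool)
    if fraction <= 0:
        return mask
    yy, xx = np.mgrid[0:height, 0:width]
    scale = np.sqrt(fraction / 0.25)
    cy, cx = 0.52 * height + rng.uniform(-2, 2), 0.5 * width + rng.uniform(-2, 2)

    def ellipse(y0, x0, ry, rx, angle=0.0):
        ca, sa = np.cos(angle), np.sin(angle)
        u = (yy - y0) * ca + (xx - x0) * sa
        v = -(yy - y0) * sa + (xx - x0) * ca
        return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0

    body_ry, body_rx = 0.16 * height * scale, 0.13 * width * scale
    mask |= ellipse(cy, cx, body_ry, body_rx)
    # Leaf lobes fanning out from the body.
    for angle in (-0.9, 0.0, 0.9):
        a = angle + rng.uniform(-0.1, 0.1)
        y0 = cy - body_ry * 0.9 - 0.10 * height * scale * np.cos(a)
        x0 = cx + 0.16 * width * scale * np.sin(a)
        mask |= ellipse(y0, x0, 0.11 * height * scale, 0.05 * width * scale, a)
    # Stem down to the pot line.
    stem_half = max(1.0, 0.012 * width * scale)
    mask |= (np.abs(xx - cx) <= stem_half) & (yy >= cy) & (yy <= cy + 0.3 * height * scale)
    return mask


def _lamp_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth halogen-like relative spectral power, peaking in the NIR."""
    g = np.exp(-0.5 * ((wavelengths - 880.0) / 400.0) ** 2)
    return 0.3 + 0.7 * g / g.max()


def render_scene(endmember: np.ndarray, cfg: SceneConfig) -> Scene:
    """Forward-model a raw line-scan cube plus dark/white frames and truth mask.

    raw = dark + gain(lambda) * illum(column) * reflectance + noise; the
    white frame images a unit-reflectance target, so calibrating the
    noiseless scene recovers the endmember exactly at plant pixels.
    Reference frames are per-spatial-line (width x bands) arrays
    broadcast across the scan direction.
    """
    wl = cfg.wavelengths
    endmember = np.asarray(endmember, dtype=float)
    if endmember.shape != wl.shape:
        raise ValueError(
            f"endmember length {endmember.size} does not match grid length {wl.size}"
        )
    rng = np.random.default_rng(cfg.seed)
    mask = _plant_silhouette(cfg.height, cfg.width, cfg.plant_fraction, rng)

    dark = np.full((cfg.width, wl.size), 100.0)
    gain = 3600.0 * _lamp_spectrum(wl)
    illum = 1.0 + cfg.illum_amplitude * np.cos(
        2.0 * np.pi * (np.arange(cfg.width) / cfg.width - 0.5)
    )
    white = dark + gain[None, :] * illum[:, None]

    refl = np.where(mask[:, :, None], endmember[None, None, :], cfg.background_reflectance)
    signal = dark[None, :, :] + gain[None, None, :] * illum[None, :, None] * refl
    noise = cfg.noise_sd * rng.standard_normal(signal.shape) if cfg.noise_sd > 0 else 0.0
    raw = HyperCube(data=signal + noise, wavelengths=wl, kind="raw")
    return Scene(raw=raw, refs=ReferenceFrames(dark=dark, white=white), truth_mask=mask)


@dataclass
class StudyConfig:
    """Design of a full synthetic study (classes, counts, rounds, days, outliers)."""

    treatments: list[TreatmentSpec] = field(default_factory=default_treatments)
    samples_per_herbicide: int = 16
    control_samples: int = 32
    rounds: int = 2
    days: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    outlier_count: int = 5
    outlier_day: int = 2
    wl_start: float = 380.0
    wl_stop: float = 1030.0
    wl_step: float = 1.2
    crop: tuple[float, float] = (460.0, 975.0)
    noise_sd: float = 0.004
    amplitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for count in (self.samples_per_herbicide, self.control_samples, self.rounds, self.outlier_count):
            if count < 0:
                raise ValueError("all design counts must be >= 0")
        days = tuple(int(d) for d in self.days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        self.days = days
        names = [t.name for t in self.treatments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate treatment names")
        unknown = [n for n in names if n not in CANONICAL_ORDER]
        if unknown:
            raise ValueError(f"unknown treatment name(s) {unknown}; expected {CANONICAL_ORDER}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop, self.wl_step)

    def to_yaml(self, path: str) -> None:
        payload = asdict(self)
        payload["treatments"] = [asdict(t) for t in self.treatments]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        treatments = [
            TreatmentSpec(
                name=t["name"],
                moa_group=t["moa_group"],
                soa_target=t["soa_target"],
                dose_g_ha=t["dose_g_ha"],
                effect_bands=tuple(EffectBand(**b) for b in t["effect_bands"]),
                severity_growth=t.get("severity_growth", 1.25),
                stress_rate=t.get("stress_rate", 0.0),
            )
            for t in payload.pop("treatments")
        ]
        payload["days"] = tuple(payload["days"])
        payload["crop"] = tuple(payload["crop"])
        return cls(treatments=treatments, **payload)


@dataclass
class StudyData:
    """Generated study: extracted spectra table plus the injected-outlier ids."""

    table: SpectraTable
    outlier_ids: list[str]


def generate_study(cfg: StudyConfig) -> StudyData:
    """Simulate the full study as extracted, smoothed, cropped mean spectra.

    One row per sample per day.  Per-sample biology (endmember
    parameter jitter, severity jitter) is drawn once per plant;
    per-measurement scatter (gain/offset) and sensor noise are drawn
    per sample-day.  Injected outliers are plants rendered necrotic
    (near-zero flat reflectance) from ``outlier_day`` onward, flagged
    in the table and listed separately.
    """
    wl = cfg.wavelengths
    crop_idx = crop_indices(wl, *cfg.crop)
    specs = {t.name: t for t in cfg.treatments}

    # Enumerate samples: per round, each herbicide then the control group.
    plan: list[tuple[int, str]] = []
    for rnd in range(1, cfg.rounds + 1):
        for spec in cfg.treatments:
            n = cfg.control_samples if spec.name == CONTROL else cfg.samples_per_herbicide
            plan.extend((rnd, spec.name) for _ in range(n))

    root = np.random.SeedSequence(cfg.seed)
    ss_biology, ss_measure, ss_outlier = root.spawn(3)
    bio_streams = [np.random.default_rng(s) for s in ss_biology.spawn(len(plan))]
    measure_rng = np.random.default_rng(ss_measure)

    counters: dict[tuple[int, str], int] = {}
    rows_X: list[np.ndarray] = []
    rows_meta: list[dict] = []
    sample_ids: list[str] = []
    treated_ids: list[str] = []

    for (rnd, name), rng in zip(plan, bio_streams):
        k = counters.get((rnd, name), 0)
        counters[(rnd, name)] = k + 1
        sample_id = f"R{rnd}_{name}_{k:02d}"
        sample_ids.append(sample_id)
        if name != CONTROL:
            treated_ids.append(sample_id)
        spec = specs[name]

        base = leaf_endmember(
            wl,
            nir_plateau=float(np.clip(rng.normal(0.55, 0.03), 0.4, 0.7)),
            red_edge_center=float(rng.normal(705.0, 2.0)),
            red_edge_width=float(np.clip(rng.normal(14.0, 1.0), 10.0, 20.0)),
            green_amp=float(np.clip(rng.normal(0.07, 0.008), 0.03, 0.12)),
            chl_red_depth=float(np.clip(rng.normal(0.025, 0.004), 0.005, 0.05)),
        )
        severity = float(np.clip(rng.normal(1.0, 0.08), 0.6, 1.4))

        for day in cfg.days:
            clean = apply_treatment_effect(
                base, wl, spec, day, severity_scale=severity * cfg.amplitude_scale
            )
            w = damage_weight(spec, day, severity_scale=severity)
            if w > 0:
                clean = (1.0 - w) * clean + w * damaged_endmember(wl)
            gain = measure_rng.normal(1.0, 0.04)
            offset = measure_rng.normal(0.0, 0.004)
            noisy = gain * clean + offset + cfg.noise_sd * measure_rng.standard_normal(wl.size)
            smooth = savgol_smooth(noisy)
            rows_X.append(smooth[crop_idx])
            rows_meta.append(
                dict(
                    sample_id=sample_id,
                    treatment=name,
                    soa=spec.soa_target,
                    moa_group=spec.moa_group,
                    dat=day,
                    round=rnd,
                    outlier=False,
                )
            )

    # Outlier injection: plants severely damaged from outlier_day onward.
    outlier_rng = np.random.default_rng(ss_outlier)
    n_out = min(cfg.outlier_count, len(treated_ids))
    outlier_ids = sorted(
        outlier_rng.choice(np.array(treated_ids), size=n_out, replace=False).tolist()
    )
    if n_out:
        necrotic_base = 0.03
        for i, meta in enumerate(rows_meta):
            if meta["sample_id"] in outlier_ids:
                meta["outlier"] = True
                if meta["dat"] >= cfg.outlier_day:
                    necro = necrotic_base + 0.002 * outlier_rng.standard_normal(crop_idx.size)
                    rows_X[i] = np.clip(necro, 1e-4, 1.0)

    table = SpectraTable(
        X=np.vstack(rows_X),
        wavelengths=wl[crop_idx],
        meta=pd.DataFrame(rows_meta),
    )
    return StudyData(table=table, outlier_ids=list(outlier_ids))
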