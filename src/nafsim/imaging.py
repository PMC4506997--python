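"""Modality rendering and dynamic-study synthesis.

Ground-truth maps (bound activity or mineral density) are turned into
modality-specific images by a point-spread-function blur, block-average
resampling to the modality's voxel size, and an optional noise model.  The
presets span the study's resolution ladder — phosphor autoradiography
(FWHM 50 μm), μPET (900 μm), μCT (30 μm), clinical PET and CT — so that the
partial-volume behaviour of each can be compared on the same phantom.

The module also carries the biexponential plasma model of tracer clearance
(fast redistribution, slow renal elimination) and the forward model of a
dynamic PET study: an irreversibly trapping tissue whose concentration obeys
C_t(t) = Ki·∫₀ᵗ C_b dτ + V·C_b(t), sampled on the 28-frame clinical schedule
(12 × 10 s, 4 × 30 s, 12 × 240 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .phantom import LABEL_SOFT_TISSUE, PlaquePhantom

__all__ = [
    "ModalityProfile",
    "ImageVolume",
    "PlasmaModel",
    "DynamicStudy",
    "MODALITY_PRESETS",
    "DEFAULT_FRAME_SCHEDULE_S",
    "FWHM_TO_SIGMA",
    "apply_modality",
    "mineral_to_hu",
    "plasma_curve",
    "plasma_integral",
    "simulate_dynamic_study",
    "default_plasma_model",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548

HU_AIR_FLOOR = -1024.0

#: Clinical dynamic frame durations in seconds: 12×10 s, 4×30 s, 12×240 s.
DEFAULT_FRAME_SCHEDULE_S: tuple[float, ...] = (10.0,) * 12 + (30.0,) * 4 + (240.0,) * 12


@dataclass(frozen=True)
class ModalityProfile:
    """Imaging characteristics of one modality.

    ``psf_fwhm`` and ``out_voxel_size`` are in μm.  ``signal`` distinguishes
    activity images (PET-like) from HU images (CT-like); quantification uses
    it to refuse unit-inconsistent operations.  ``detection_floor`` records,
    for CT-like modalities, the smallest object scale (μm) the modality is
    considered able to represent — metadata for reporting, not a filter.
    """

    name: str
    psf_fwhm: float
    out_voxel_size: float
    signal: Literal["activity", "hu"]
    noise_model: Literal["none", "gaussian", "poisson"] = "none"
    noise_scale: float = 0.0
    detection_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be non-negative")
        if self.out_voxel_size <= 0:
            raise ValueError("out_voxel_size must be positive")


#: Resolution ladder used throughout.  μPET/μCT FWHM are the printed scanner
#: resolutions (900 / 30 μm) at their native grids (300 / 22 μm); clinical
#: PET/CT resolutions are conventional values for the scanner class and are
#: not study-specific.  Autoradiography/histology approximate digitized
#: phosphor-screen and slide scans.
MODALITY_PRESETS: dict[str, ModalityProfile] = {
    "autoradiography": ModalityProfile(
        "autoradiography", 50.0, 25.0, "activity", "poisson", 1e3
    ),
    "histology": ModalityProfile("histology", 25.0, 25.0, "hu", "gaussian", 15.0),
    "micro_pet": ModalityProfile("micro_pet", 900.0, 300.0, "activity", "poisson", 1e3),
    "micro_ct": ModalityProfile(
        "micro_ct", 30.0, 22.0, "hu", "gaussian", 15.0, detection_floor=50.0
    ),
    "clinical_pet": ModalityProfile(
        "clinical_pet", 4500.0, 2000.0, "activity", "poisson", 1e3
    ),
    "clinical_ct": ModalityProfile(
        "clinical_ct", 600.0, 500.0, "hu", "gaussian", 15.0, detection_floor=200.0
    ),
    "truth_activity": ModalityProfile("truth_activity", 0.0, 1.0, "activity"),
    "truth_hu": ModalityProfile("truth_hu", 0.0, 1.0, "hu"),
}


@dataclass
class ImageVolume:
    """A rendered image with voxel size (μm) and the profile that made it."""

    grid: np.ndarray
    voxel_size: float
    modality: ModalityProfile

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("image contains non-finite values")
        if self.modality.signal == "hu" and np.any(self.grid < HU_AIR_FLOOR):
            raise ValueError(f"HU values below the air floor {HU_AIR_FLOOR}")

    @property
    def extent(self) -> tuple[float, ...]:
        return tuple(n * self.voxel_size for n in self.grid.shape)


def _block_average(grid: np.ndarray, factor: int) -> np.ndarray:
    """Mean over non-overlapping ``factor``-sized blocks, zero-padding edges.

    Zero padding keeps the integrated signal exactly conserved.
    """
    if factor == 1:
        return grid.copy()
    pads = [(0, (-n) % factor) for n in grid.shape]
    g = np.pad(grid, pads, mode="constant")
    for ax in range(g.ndim):
        n = g.shape[ax]
        g = g.reshape(
            g.shape[:ax] + (n // factor, factor) + g.shape[ax + 1 :]
        ).mean(axis=ax + 1)
    return g


def apply_modality(
    truth, profile: ModalityProfile, seed: Optional[int] = None
) -> ImageVolume:
    """Render a ground-truth map through one modality.

    ``truth`` is any object with ``grid`` and ``voxel_size`` attributes
    (an :class:`~nafsim.adsorption.ActivityMap` or an :class:`ImageVolume`).
    The pipeline is: Gaussian PSF (σ = FWHM/2.3548), block-average resampling
    by the integer factor ``round(out_voxel_size / voxel_size)`` (the
    *effective* output voxel size, ``factor·voxel_size``, is recorded on the
    result), then the profile's noise model seeded by ``seed``.  With
    ``noise_model='none'`` the total integrated signal is conserved exactly.
    """
    in_vox = float(truth.voxel_size)
    if profile.out_voxel_size < in_vox:
        raise ValueError(
            f"output voxel {profile.out_voxel_size} μm is finer than the "
            f"truth grid ({in_vox} μm)"
        )
    factor = max(1, int(round(profile.out_voxel_size / in_vox)))

    grid = np.asarray(truth.grid, dtype=float)
    if profile.psf_fwhm > 0:
        sigma_vox = profile.psf_fwhm * FWHM_TO_SIGMA / in_vox
        grid = ndimage.gaussian_filter(grid, sigma=sigma_vox)
    grid = _block_average(grid, factor)

    if profile.noise_model == "gaussian" and profile.noise_scale > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, profile.noise_scale, size=grid.shape)
    elif profile.noise_model == "poisson" and profile.noise_scale > 0:
        rng = np.random.default_rng(seed)
        grid = rng.poisson(np.clip(grid, 0, None) * profile.noise_scale)
        grid = grid / profile.noise_scale

    if profile.signal == "hu":
        grid = np.clip(grid, HU_AIR_FLOOR, None)

    eff = replace(profile, out_voxel_size=factor * in_vox)
    return ImageVolume(grid=grid, voxel_size=factor * in_vox, modality=eff)


def mineral_to_hu(
    phantom: PlaquePhantom,
    hu_bg: float = 0.0,
    hu_soft: float = 40.0,
    hu_calc: float = 1300.0,
) -> ImageVolume:
    """Map phantom labels to a CT-density (HU) field at the truth grid.

    Background renders as a water-equivalent bath (0 HU), soft plaque tissue
    at 40 HU, and mineral at ``hu_calc`` scaled by each deposit's relative
    mineral density — monotone in density and, at the defaults, comfortably
    above the 1,000 HU calcification rule so that partial volume rather than
    the mapping governs detectability.
    """
    grid = np.full(phantom.grid.shape, hu_bg, dtype=float)
    grid[phantom.grid == LABEL_SOFT_TISSUE] = hu_soft
    for i, dep in enumerate(phantom.deposits):
        grid[phantom.deposit_mask(i)] = hu_calc * dep.mineral_density
    profile = replace(MODALITY_PRESETS["truth_hu"], out_voxel_size=phantom.voxel_size)
    return ImageVolume(grid=grid, voxel_size=phantom.voxel_size, modality=profile)


# --------------------------------------------------------------------------
# Plasma model and dynamic studies


@dataclass(frozen=True)
class PlasmaModel:
    """Biexponential blood-pool clearance C(t) = A1·e^(−λ1 t) + A2·e^(−λ2 t).

    λ1 is the fast redistribution rate, λ2 the slow elimination rate
    (min⁻¹); amplitudes are in arbitrary activity units.
    ``plasma_to_blood_ratio`` folds the plasma/whole-blood partition into a
    single factor: blood concentration = plasma / ratio.
    """

    a1: float = 0.9
    a2: float = 0.1
    lam1: float = 0.25
    lam2: float = 0.00851384
    plasma_to_blood_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("plasma amplitudes must be non-negative")
        if not self.lam1 > self.lam2 > 0:
            raise ValueError("plasma rates must satisfy λ1 > λ2 > 0")
        if self.plasma_to_blood_ratio <= 0:
            raise ValueError("plasma_to_blood_ratio must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.lam1 * t) + self.a2 * np.exp(-self.lam2 * t)


def default_plasma_model() -> PlasmaModel:
    """Default clearance: 60-min plasma activity is 6% of the peak.

    λ2 solves C(60)/C(0) = 0.06 given A1 = 0.9, A2 = 0.1, λ1 = 0.25 —
    the midpoint of the observed 4–8% range.
    """
    return PlasmaModel()


def plasma_curve(model: PlasmaModel, times):
    """Evaluate the plasma model as a time-activity curve.

    Returns a :class:`~nafsim.kinetics.TimeActivityCurve` labeled ``plasma``.
    """
    from .kinetics import TimeActivityCurve

    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return TimeActivityCurve(times=t, values=model(t), label="plasma")


def plasma_integral(model: PlasmaModel, t) -> np.ndarray:
    """Closed-form ∫₀ᵗ C(τ) dτ for the biexponential."""
    t = np.asarray(t, dtype=float)
    return _exp_integral(model.a1, model.lam1, t) + _exp_integral(
        model.a2, model.lam2, t
    )


def _exp_integral(a: float, lam: float, t: np.ndarray) -> np.ndarray:
    return a / lam * -np.expm1(-lam * t)


def _double_integral(model: PlasmaModel, t: np.ndarray) -> np.ndarray:
    """Closed-form ∫₀ᵗ ∫₀^s C(τ) dτ ds."""
    out = np.zeros_like(np.asarray(t, dtype=float))
    for a, lam in ((model.a1, model.lam1), (model.a2, model.lam2)):
        out = out + a / lam * (t + np.expm1(-lam * t) / lam)
    return out


@dataclass
class DynamicStudy:
    """A synthesized dynamic PET study (frame-binned blood and tissue TACs)."""

    frame_starts_s: np.ndarray
    frame_ends_s: np.ndarray
    t_mid_min: np.ndarray
    plasma: "object"  # TimeActivityCurve
    tissue: "object"  # TimeActivityCurve
    ki: float
    v: float

    @property
    def frame_durations_min(self) -> np.ndarray:
        return (self.frame_ends_s - self.frame_starts_s) / 60.0


def simulate_dynamic_study(
    ki: float,
    v: float,
    plasma: PlasmaModel,
    schedule_s: Sequence[float] = DEFAULT_FRAME_SCHEDULE_S,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
) -> DynamicStudy:
    """Forward-model an irreversible-trapping dynamic study.

    Tissue concentration follows C_t(t) = Ki·∫₀ᵗ C_b dτ + V·C_b(t) with the
    blood curve from the plasma model.  Frame values are duration-weighted
    means computed from the closed-form integrals of the biexponential (no
    quadrature error); time stamps are frame midpoints in minutes.  Optional
    multiplicative Gaussian noise (σ relative) perturbs the tissue frames.
    """
    from .kinetics import TimeActivityCurve

    if ki < 0:
        raise ValueError("Ki must be non-negative")
    durations = np.asarray(schedule_s, dtype=float)
    if durations.size == 0:
        raise ValueError("frame schedule is empty")
    if np.any(durations <= 0):
        raise ValueError("frame durations must be positive")

    ends_s = np.cumsum(durations)
    starts_s = ends_s - durations
    a_min, b_min = starts_s / 60.0, ends_s / 60.0
    dur_min = b_min - a_min
    t_mid = 0.5 * (a_min + b_min)

    ratio = plasma.plasma_to_blood_ratio
    # frame means of C_b and of ∫C_b, exactly
    mean_cb = (plasma_integral(plasma, b_min) - plasma_integral(plasma, a_min)) / (
        dur_min * ratio
    )
    mean_icb = (_double_integral(plasma, b_min) - _double_integral(plasma, a_min)) / (
        dur_min * ratio
    )
    tissue_vals = ki * mean_icb + v * mean_cb

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        tissue_vals = tissue_vals * (1.0 + rng.normal(0.0, noise_sigma, t_mid.shape))
        tissue_vals = np.clip(tissue_vals, 0.0, None)

    return DynamicStudy(
        frame_starts_s=starts_s,
        frame_ends_s=ends_s,
        t_mid_min=t_mid,
        plasma=TimeActivityCurve(times=t_mid, values=mean_cb, label="blood"),
        tissue=TimeActivityCurve(times=t_mid, values=tissue_vals, label="tissue"),
        ki=ki,
        v=v,
    )
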