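"""Image quantification: thresholding, co-localization and transect profiles.

Reproduces the image-analysis pipeline applied to the tracer and mineral
channels: automatic Otsu / Li thresholding, the threshold → Gaussian blur →
re-threshold mask refinement that absorbs resolution differences between
modalities, Pearson correlation of binary masks, the three-way PET/CT
accounting (PET+/CT−, PET+/CT+, PET−/CT+ as percentages of the union of
positives), the ≥1,000 HU calcification rule, and linear transect profiling
across paired PET/CT volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .imaging import ImageVolume

__all__ = [
    "BinaryMask",
    "TriClassResult",
    "TransectProfile",
    "ThresholdError",
    "otsu_threshold",
    "li_threshold",
    "mask_pipeline",
    "pearson_masks",
    "tri_class",
    "hu_calcification_mask",
    "transect_profile",
    "upsample_mask",
]


class ThresholdError(ValueError):
    """The image cannot be thresholded (constant, or iteration failed)."""


@dataclass
class BinaryMask:
    """Boolean segmentation with the provenance of how it was made."""

    grid: np.ndarray
    voxel_size: float
    provenance: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def n_positive(self) -> int:
        return int(self.grid.sum())


@dataclass
class TriClassResult:
    """Voxel counts and percentages of PET+/CT−, PET+/CT+, PET−/CT+.

    Percentages are taken over the union of positives, so the three classes
    sum to 100.
    """

    counts: dict[str, int]
    percentages: dict[str, float]


@dataclass
class TransectProfile:
    """Paired PET/CT intensity profiles along a line, positions in mm."""

    positions_mm: np.ndarray
    pet_values: np.ndarray
    ct_values: np.ndarray


def _check_separable(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float).ravel()
    if arr.size == 0 or np.min(arr) == np.max(arr):
        raise ThresholdError(
            "image is constant: no threshold separates two classes"
        )
    return arr


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class histogram variance (Otsu).

    The mask convention throughout this module is ``value > threshold``;
    ties among maximizing cut points resolve to the lowest.
    """
    arr = _check_separable(image)
    return float(threshold_otsu(arr, nbins=n_bins))


def li_threshold(
    image: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Minimum-cross-entropy threshold via the Li–Tam iteration.

    Starting from the image mean, each step maps the current threshold to the
    logarithmic mean of the two class means,
    ``t' = (μ_low − μ_high) / (ln μ_low − ln μ_high)``, a fixed-point scheme
    that converges to a minimum of the cross entropy between the image and
    its two-level reconstruction.  Requires non-negative values (the cross
    entropy involves logarithms of class means).  Raises with the iterate
    trace if ``|Δt| < tol`` is not reached within ``max_iter`` steps.
    """
    arr = _check_separable(image)
    if np.any(arr < 0):
        raise ValueError("Li thresholding requires non-negative image values")

    t = float(arr.mean())
    trace = [t]
    for _ in range(max_iter):
        low = arr[arr <= t]
        high = arr[arr > t]
        if high.size == 0:  # threshold drifted past the maximum
            t_new = float(arr.max())
        else:
            mu_high = float(high.mean())
            mu_low = float(low.mean()) if low.size else 0.0
            if mu_low <= 0.0:
                # limit of the log-mean as the lower class mean → 0
                t_new = 0.0
            elif np.isclose(mu_low, mu_high):
                t_new = mu_low
            else:
                t_new = (mu_low - mu_high) / (np.log(mu_low) - np.log(mu_high))
        trace.append(t_new)
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    raise ThresholdError(
        f"Li iteration did not converge within {max_iter} steps; "
        f"iterate trace: {[round(v, 6) for v in trace]}"
    )


ThresholdSpec = Union[str, tuple[str, float]]


def _apply_threshold(image: np.ndarray, spec: ThresholdSpec) -> tuple[np.ndarray, str]:
    if isinstance(spec, tuple):
        method, level = spec
        if method != "manual":
            raise ValueError(f"unknown threshold spec {spec!r}")
        return np.asarray(image) > level, f"manual(level={level})"
    if spec == "otsu":
        t = otsu_threshold(np.asarray(image))
        return np.asarray(image) > t, f"otsu(t={t:.6g})"
    if spec == "li":
        t = li_threshold(np.asarray(image))
        return np.asarray(image) > t, f"li(t={t:.6g})"
    raise ValueError(f"unknown threshold method {spec!r}")


def mask_pipeline(
    image,
    first_threshold: ThresholdSpec = "otsu",
    blur_sigma: float = 20.0,
    second_threshold: ThresholdSpec = "li",
) -> BinaryMask:
    """Binarize, blur the binary field, and re-binarize.

    This is the segmentation-mask recipe of the 2D pipeline: an automatic
    first threshold, a Gaussian blur of the resulting binary image
    (σ in pixels of the analyzed image, default 20), and a second automatic
    threshold of the blurred field.  The blur erases isolated positives that
    are small relative to genuine structures and dilates mask boundaries,
    absorbing resolution mismatch between co-registered channels.  With
    ``blur_sigma=0`` the result equals the plain first-threshold mask.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    grid = image.grid if isinstance(image, ImageVolume) else np.asarray(image)
    voxel = image.voxel_size if isinstance(image, ImageVolume) else 1.0

    binary, prov1 = _apply_threshold(grid, first_threshold)
    if blur_sigma == 0:
        return BinaryMask(binary, voxel, provenance=f"{prov1} | no blur")
    blurred = ndimage.gaussian_filter(binary.astype(float), sigma=blur_sigma)
    mask, prov2 = _apply_threshold(blurred, second_threshold)
    return BinaryMask(
        mask, voxel, provenance=f"{prov1} | gaussian(sigma={blur_sigma}px) | {prov2}"
    )


def pearson_masks(a: BinaryMask, b: BinaryMask) -> float:
    """Pearson correlation of two binary masks over their {0,1} voxel values."""
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"mask shapes differ: {a.grid.shape} vs {b.grid.shape}")
    for name, m in (("first", a), ("second", b)):
        if m.grid.all() or not m.grid.any():
            raise ValueError(f"{name} mask is constant; correlation undefined")
    r, _ = stats.pearsonr(a.grid.ravel().astype(float), b.grid.ravel().astype(float))
    return float(r)


def tri_class(pet: BinaryMask, ct: BinaryMask) -> TriClassResult:
    """Partition the union of positives into PET-only, both, CT-only."""
    if pet.grid.shape != ct.grid.shape:
        raise ValueError(f"mask shapes differ: {pet.grid.shape} vs {ct.grid.shape}")
    if pet.voxel_size != ct.voxel_size:
        raise ValueError("masks have different voxel sizes; resample first")
    p, c = pet.grid, ct.grid
    counts = {
        "pet_only": int((p & ~c).sum()),
        "both": int((p & c).sum()),
        "ct_only": int((~p & c).sum()),
    }
    union = sum(counts.values())
    if union == 0:
        raise ValueError("both masks are empty; tri-class percentages are undefined")
    percentages = {k: 100.0 * v / union for k, v in counts.items()}
    return TriClassResult(counts=counts, percentages=percentages)


def hu_calcification_mask(ct: ImageVolume, threshold_hu: float = 1000.0) -> BinaryMask:
    """Calcification mask by the HU rule: positive iff value ≥ threshold."""
    if ct.modality.signal != "hu":
        raise ValueError(
            f"HU thresholding applied to a non-CT image "
            f"(modality {ct.modality.name!r} carries {ct.modality.signal!r} units)"
        )
    return BinaryMask(
        ct.grid >= threshold_hu,
        ct.voxel_size,
        provenance=f"hu>= {threshold_hu} ({ct.modality.name})",
    )


def upsample_mask(mask: BinaryMask, target_shape: tuple, target_voxel: float) -> BinaryMask:
    """Nearest-neighbour upsampling of a mask onto a finer grid.

    The integer repetition factor is ``round(voxel_size / target_voxel)``;
    the repeated grid is cropped to ``target_shape`` (renders are zero-padded
    at the high end, so cropping discards padding only).
    """
    factor = max(1, int(round(mask.voxel_size / target_voxel)))
    g = mask.grid
    for ax in range(g.ndim):
        g = np.repeat(g, factor, axis=ax)
    g = g[tuple(slice(0, n) for n in target_shape)]
    if g.shape != tuple(target_shape):
        raise ValueError(
            f"mask upsamples to {g.shape}, smaller than target {tuple(target_shape)}"
        )
    return BinaryMask(
        g, target_voxel, provenance=f"{mask.provenance} | upsampled x{factor}"
    )


def transect_profile(
    pet: ImageVolume,
    ct: ImageVolume,
    start,
    end,
    n_samples: int = 200,
) -> TransectProfile:
    """Sample both volumes along a straight line between physical points.

    ``start`` and ``end`` are physical coordinates in μm; both must lie
    inside both volumes.  Values are linearly interpolated at ``n_samples``
    evenly spaced points; positions are reported in mm from ``start``.  Used
    for the rim/core comparison across macrocalcific deposits, where the PET
    profile shows two rim maxima around a cold core while CT shows a plateau.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    for vol in (pet, ct):
        ext = np.asarray(vol.extent)
        if start.size != len(ext) or end.size != len(ext):
            raise ValueError("transect endpoints must match volume dimensionality")
        for p in (start, end):
            if np.any(p < 0) or np.any(p > ext):
                raise ValueError(
                    f"transect endpoint {p.tolist()} μm exits the volume "
                    f"(extent {ext.tolist()} μm)"
                )

    frac = np.linspace(0.0, 1.0, n_samples)
    points = start[None, :] + frac[:, None] * (end - start)[None, :]
    positions_mm = np.linalg.norm(points - start[None, :], axis=1) / 1000.0

    def sample(vol: ImageVolume) -> np.ndarray:
        coords = (points / vol.voxel_size - 0.5).T  # physical → index space
        return ndimage.map_coordinates(
            vol.grid.astype(float), coords, order=1, mode="nearest"
        )

    return TransectProfile(
        positions_mm=positions_mm, pet_values=sample(pet), ct_values=sample(ct)
    )
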