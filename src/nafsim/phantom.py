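"""Digital carotid-plaque phantoms with micro- and macrocalcific deposits.

A phantom is a labeled voxel grid (background / soft tissue / calcified
mineral) plus the ground-truth geometry of every calcific deposit, standing in
for an endarterectomy specimen.  Deposits are spheres (discs in 2D) so that
rasterized quantities — volumes, surface shells, per-deposit signal — can be
checked against closed forms.  The size convention of the field is applied on
the *diameter*: nodules under 50 μm are microcalcifications, 50 μm and above
are macrocalcifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MICRO_MACRO_DIAMETER_UM",
    "CalcificDeposit",
    "PlaquePhantom",
    "PhantomConfig",
    "PlacementError",
    "generate_phantom",
    "classify_deposit",
    "surface_shell",
    "section_phantom",
]

#: Diameter (μm) separating micro- from macrocalcification.
MICRO_MACRO_DIAMETER_UM = 50.0

LABEL_BACKGROUND = 0
LABEL_SOFT_TISSUE = 1
LABEL_CALCIFIED = 2


class PlacementError(RuntimeError):
    """A deposit could not be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class CalcificDeposit:
    """A spherical (2D: circular) calcific deposit.

    Parameters
    ----------
    center:
        Physical coordinates of the deposit center in μm (one value per axis).
    radius:
        Radius in μm; must be positive.
    mineral_density:
        Relative hydroxyapatite density in [0, 1]; scales the rendered CT
        density of the deposit.
    """

    center: tuple[float, ...]
    radius: float
    mineral_density: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"deposit radius must be positive, got {self.radius}")
        if not 0.0 <= self.mineral_density <= 1.0:
            raise ValueError(
                f"mineral_density must lie in [0, 1], got {self.mineral_density}"
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class PlaquePhantom:
    """Labeled grid of a synthetic plaque plus ground-truth deposits.

    ``grid`` holds integer labels (0 background, 1 soft tissue, 2 calcified);
    ``deposit_map`` assigns each calcified voxel to its owning deposit
    (0 = none, i+1 = ``deposits[i]``).  Voxels are isotropic with edge
    ``voxel_size`` μm; a voxel's physical position is its center,
    ``(index + 0.5) * voxel_size``, on the half-open domain ``[0, extent)``.
    """

    grid: np.ndarray
    voxel_size: float
    deposits: list[CalcificDeposit]
    deposit_map: np.ndarray
    exposed_deposits: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.grid.ndim not in (2, 3):
            raise ValueError("phantom grid must be 2D or 3D")
        bad = set(np.unique(self.grid)) - {
            LABEL_BACKGROUND,
            LABEL_SOFT_TISSUE,
            LABEL_CALCIFIED,
        }
        if bad:
            raise ValueError(f"grid contains invalid labels {sorted(bad)}")

    @property
    def dimensionality(self) -> int:
        return self.grid.ndim

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical domain size per axis, μm."""
        return tuple(n * self.voxel_size for n in self.grid.shape)

    def calcified_mask(self) -> np.ndarray:
        return self.grid == LABEL_CALCIFIED

    def deposit_mask(self, index: int) -> np.ndarray:
        """Boolean mask of the voxels owned by ``deposits[index]``."""
        if not 0 <= index < len(self.deposits):
            raise IndexError(f"no deposit with index {index}")
        return self.deposit_map == index + 1

    def deposit_index(self, deposit: CalcificDeposit) -> int:
        for i, d in enumerate(self.deposits):
            if d == deposit:
                return i
        raise ValueError("deposit is not part of this phantom")


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for :func:`generate_phantom`.

    ``domain_size_um`` fixes dimensionality (2 or 3 entries).  Radius ranges
    are inclusive bounds in μm and must respect the diameter-based size
    convention: every micro radius < 25 μm, every macro radius ≥ 25 μm.
    The number density and radius distribution of deposits in plaque tissue
    are not standardized; the defaults describe a deliberately deposit-rich
    8 × 8 mm section with a handful of macroscopic nodules and a dispersed
    population of microcalcifications.
    """

    domain_size_um: tuple[float, ...] = (8000.0, 8000.0)
    voxel_size_um: float = 5.0
    n_micro: int = 150
    n_macro: int = 6
    micro_radius_um: tuple[float, float] = (6.0, 24.0)
    macro_radius_um: tuple[float, float] = (150.0, 1200.0)
    mineral_density_range: tuple[float, float] = (0.85, 1.0)
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if len(self.domain_size_um) not in (2, 3):
            raise ValueError("domain_size_um must have 2 or 3 entries")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        for name, (lo, hi) in (
            ("micro_radius_um", self.micro_radius_um),
            ("macro_radius_um", self.macro_radius_um),
        ):
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        half = MICRO_MACRO_DIAMETER_UM / 2.0
        if self.n_micro and self.micro_radius_um[1] >= half:
            raise ValueError(
                "micro radius range must classify as micro "
                f"(radius < {half} μm), got {self.micro_radius_um}"
            )
        if self.n_macro and self.macro_radius_um[0] < half:
            raise ValueError(
                "macro radius range must classify as macro "
                f"(radius >= {half} μm), got {self.macro_radius_um}"
            )
        if self.n_micro and self.voxel_size_um > self.micro_radius_um[0]:
            raise ValueError(
                f"voxel_size {self.voxel_size_um} μm is too coarse to represent the "
                f"smallest requested micro deposit (radius {self.micro_radius_um[0]} μm); "
                "reduce voxel_size_um or raise the micro radius range"
            )
        if self.n_micro < 0 or self.n_macro < 0:
            raise ValueError("deposit counts must be non-negative")


def classify_deposit(deposit: CalcificDeposit) -> Literal["micro", "macro"]:
    """Classify a deposit by the <50 μm / ≥50 μm diameter convention."""
    if deposit.radius <= 0:  # defensive; the dataclass already rejects this
        raise ValueError("deposit radius must be positive")
    return "micro" if deposit.diameter < MICRO_MACRO_DIAMETER_UM else "macro"


def _voxel_centers(n: int, voxel_size: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * voxel_size


def _rasterize(
    shape: tuple[int, ...], voxel_size: float, deposits: Sequence[CalcificDeposit]
) -> np.ndarray:
    """Per-voxel deposit ownership (0 = none, i+1 = deposit i).

    A voxel belongs to a deposit when its center lies in the closed ball.
    Deposits are pairwise disjoint by construction, so ownership is unique.
    """
    owner = np.zeros(shape, dtype=np.int32)
    axes = [_voxel_centers(n, voxel_size) for n in shape]
    for i, dep in enumerate(deposits):
        lo = [
            max(0, int((c - dep.radius) / voxel_size) - 1)
            for c in dep.center
        ]
        hi = [
            min(n, int((c + dep.radius) / voxel_size) + 2)
            for c, n in zip(dep.center, shape)
        ]
        grids = np.meshgrid(
            *[ax[l:h] for ax, l, h in zip(axes, lo, hi)], indexing="ij"
        )
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, dep.center))
        sel = tuple(slice(l, h) for l, h in zip(lo, hi))
        owner[sel][dist2 <= dep.radius**2] = i + 1
    return owner


def generate_phantom(config: PhantomConfig, seed: int) -> PlaquePhantom:
    """Place disjoint spherical deposits in a soft-tissue block.

    Macro deposits are placed first, then micro deposits; every deposit must
    fit entirely inside the domain and keep a one-voxel gap to all previously
    placed deposits (bounded rejection sampling, ``config.max_attempts`` tries
    per deposit).  Identical ``(config, seed)`` yields an identical phantom.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(config.domain_size_um, dtype=float)
    shape = tuple(int(round(e / config.voxel_size_um)) for e in extent)

    deposits: list[CalcificDeposit] = []
    gap = config.voxel_size_um  # keep rasterized deposits from touching

    def place(kind: str, count: int, rrange: tuple[float, float]) -> None:
        for k in range(count):
            for _ in range(config.max_attempts):
                r = float(rng.uniform(*rrange))
                if np.any(extent < 2 * r):
                    continue
                center = tuple(
                    float(rng.uniform(r, e - r)) for e in extent
                )
                ok = all(
                    np.linalg.norm(np.subtract(center, d.center)) > r + d.radius + gap
                    for d in deposits
                )
                if ok:
                    rho = float(rng.uniform(*config.mineral_density_range))
                    deposits.append(
                        CalcificDeposit(center=center, radius=r, mineral_density=rho)
                    )
                    break
            else:
                raise PlacementError(
                    f"could not place {kind} deposit {k + 1}/{count} "
                    f"(radius range {rrange} μm) after {config.max_attempts} attempts; "
                    "reduce deposit count or radii"
                )

    place("macro", config.n_macro, config.macro_radius_um)
    place("micro", config.n_micro, config.micro_radius_um)

    owner = _rasterize(shape, config.voxel_size_um, deposits)
    grid = np.full(shape, LABEL_SOFT_TISSUE, dtype=np.uint8)
    grid[owner > 0] = LABEL_CALCIFIED
    return PlaquePhantom(
        grid=grid,
        voxel_size=config.voxel_size_um,
        deposits=deposits,
        deposit_map=owner,
    )


def surface_shell(
    phantom: PlaquePhantom, deposit: CalcificDeposit, depth: float
) -> np.ndarray:
    """Voxel mask of the outer shell of ``deposit`` accessible from outside.

    The shell consists of the deposit's voxels within ``depth`` μm (Euclidean,
    center-to-center, via distance transform) of a non-calcified voxel; for
    ``depth >= radius`` the shell is the whole deposit.  The rasterized shell
    fraction of a sphere approaches the analytic ``1 − ((R−d)/R)³`` as the
    voxel size shrinks.
    """
    if depth <= 0:
        raise ValueError(f"shell depth must be positive, got {depth}")
    idx = phantom.deposit_index(deposit)
    dep_mask = phantom.deposit_mask(idx)
    if depth >= deposit.radius:
        return dep_mask
    dist = ndimage.distance_transform_edt(
        phantom.calcified_mask(), sampling=phantom.voxel_size
    )
    return dep_mask & (dist <= depth)


def section_phantom(
    phantom: PlaquePhantom, thickness: float, axis: int = 0
) -> list[PlaquePhantom]:
    """Cut a 3D phantom into serial sections of the given thickness.

    Sections tile the volume along ``axis`` without overlap (the last section
    may be thinner); every calcified voxel appears in exactly one section.
    Each section's ``exposed_deposits`` lists the indices of deposits whose
    interior is newly opened at that section's cut faces, i.e. deposits that
    straddle a cut plane — the mechanism by which sectioning grants the tracer
    access to macrocalcification cores.
    """
    if phantom.dimensionality != 3:
        raise ValueError("section_phantom requires a 3D phantom")
    if thickness < phantom.voxel_size:
        raise ValueError(
            f"section thickness {thickness} μm is below the voxel size "
            f"{phantom.voxel_size} μm"
        )
    per = int(round(thickness / phantom.voxel_size))
    n = phantom.grid.shape[axis]
    starts = list(range(0, n, per))

    sections: list[PlaquePhantom] = []
    for s in starts:
        e = min(s + per, n)
        sel = [slice(None)] * 3
        sel[axis] = slice(s, e)
        sub_grid = phantom.grid[tuple(sel)]
        sub_owner = phantom.deposit_map[tuple(sel)]
        exposed = set()
        for cut in (s, e):
            if cut in (0, n):
                continue  # outer faces expose nothing new
            before = [slice(None)] * 3
            after = [slice(None)] * 3
            before[axis] = slice(cut - 1, cut)
            after[axis] = slice(cut, cut + 1)
            a = np.unique(phantom.deposit_map[tuple(before)])
            b = np.unique(phantom.deposit_map[tuple(after)])
            exposed |= {int(v) - 1 for v in np.intersect1d(a, b) if v > 0}
        squeeze = sub_grid.shape[axis] == 1
        sections.append(
            PlaquePhantom(
                grid=np.squeeze(sub_grid, axis=axis) if squeeze else sub_grid.copy(),
                voxel_size=phantom.voxel_size,
                deposits=list(phantom.deposits),
                deposit_map=(
                    np.squeeze(sub_owner, axis=axis) if squeeze else sub_owner.copy()
                ),
                exposed_deposits=tuple(sorted(exposed)),
            )
        )
    return sections
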