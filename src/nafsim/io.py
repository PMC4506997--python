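"""File I/O: NIfTI volumes, TIFF sections, CSV tables, JSON records.

Conventions
-----------
* Volumes are NIfTI with the voxel edge stored in the header zooms and the
  string ``units=um`` in the description (grids here are micrometre-scale,
  far below NIfTI's customary millimetres).  2D grids are written as
  single-slice 3D volumes and squeezed back on read.
* Phantoms carry a JSON sidecar with the deposit list and a companion
  deposit-ownership volume, so a write/read roundtrip reconstructs the full
  ground truth.
* Time-activity curves and dynamic studies are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .adsorption import ActivityMap
from .imaging import DynamicStudy, ImageVolume, ModalityProfile
from .kinetics import TimeActivityCurve
from .phantom import CalcificDeposit, PlaquePhantom
from .quantification import TransectProfile, TriClassResult

__all__ = [
    "FileFormatError",
    "write_phantom",
    "read_phantom",
    "write_activity_map",
    "read_activity_map",
    "write_image",
    "read_image",
    "write_sections_tiff",
    "write_tac",
    "read_tac",
    "write_dynamic_study",
    "read_dynamic_study",
    "write_tri_class",
    "read_tri_class",
    "write_transect",
    "read_transect",
    "write_json_record",
    "read_json_record",
]

PathLike = Union[str, Path]


class FileFormatError(RuntimeError):
    """A file could not be parsed as the expected artifact."""


def _write_nifti(grid: np.ndarray, voxel_size: float, path: Path) -> None:
    data = np.asarray(grid)
    if data.ndim == 2:
        data = data[..., None]
    img = nib.Nifti1Image(data, affine=np.diag([voxel_size] * 3 + [1.0]))
    img.header.set_zooms((voxel_size,) * 3)
    img.header["descrip"] = b"units=um"
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, float]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        voxel = float(img.header.get_zooms()[0])
    except Exception as exc:
        raise FileFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return data, voxel


def write_phantom(phantom: PlaquePhantom, out_dir: PathLike, stem: str = "phantom") -> Path:
    """Write labels, deposit ownership and a JSON deposit sidecar; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_nifti(phantom.grid.astype(np.uint8), phantom.voxel_size, out / f"{stem}.nii")
    _write_nifti(
        phantom.deposit_map.astype(np.int32),
        phantom.voxel_size,
        out / f"{stem}_deposits.nii",
    )
    sidecar = {
        "voxel_size_um": phantom.voxel_size,
        "exposed_deposits": list(phantom.exposed_deposits),
        "deposits": [
            {
                "center_um": list(d.center),
                "radius_um": d.radius,
                "mineral_density": d.mineral_density,
            }
            for d in phantom.deposits
        ],
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_phantom(in_dir: PathLike, stem: str = "phantom") -> PlaquePhantom:
    src = Path(in_dir)
    grid, voxel = _read_nifti(src / f"{stem}.nii")
    owner, _ = _read_nifti(src / f"{stem}_deposits.nii")
    try:
        meta = json.loads((src / f"{stem}.json").read_text())
        deposits = [
            CalcificDeposit(
                center=tuple(d["center_um"]),
                radius=float(d["radius_um"]),
                mineral_density=float(d["mineral_density"]),
            )
            for d in meta["deposits"]
        ]
        exposed = tuple(meta.get("exposed_deposits", []))
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FileFormatError(
            f"phantom sidecar {src / f'{stem}.json'} is malformed: {exc}"
        ) from exc
    return PlaquePhantom(
        grid=grid.astype(np.uint8),
        voxel_size=voxel,
        deposits=deposits,
        deposit_map=owner.astype(np.int32),
        exposed_deposits=exposed,
    )


def write_activity_map(amap: ActivityMap, path: PathLike) -> Path:
    path = Path(path)
    _write_nifti(amap.grid.astype(np.float64), amap.voxel_size, path)
    path.with_suffix(".json").write_text(
        json.dumps({"voxel_size_um": amap.voxel_size, "time_min": amap.time})
    )
    return path


def read_activity_map(path: PathLike) -> ActivityMap:
    path = Path(path)
    grid, voxel = _read_nifti(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
        time = float(meta["time_min"])
    except (FileNotFoundError, KeyError, json.JSONDecodeError) as exc:
        raise FileFormatError(f"activity sidecar for {path} is malformed: {exc}") from exc
    return ActivityMap(grid=grid, voxel_size=voxel, time=time)


def write_image(image: ImageVolume, path: PathLike) -> Path:
    path = Path(path)
    _write_nifti(image.grid.astype(np.float64), image.voxel_size, path)
    path.with_suffix(".json").write_text(
        json.dumps(dataclasses.asdict(image.modality))
    )
    return path


def read_image(path: PathLike) -> ImageVolume:
    path = Path(path)
    grid, voxel = _read_nifti(path)
    try:
        meta = json.loads(path.with_suffix(".json").read_text())
        profile = ModalityProfile(**meta)
    except (FileNotFoundError, TypeError, json.JSONDecodeError) as exc:
        raise FileFormatError(f"modality sidecar for {path} is malformed: {exc}") from exc
    return ImageVolume(grid=grid, voxel_size=voxel, modality=profile)


def read_2d_image(
    path: PathLike,
    pixel_size_um: float = 1.0,
    signal: str = "activity",
) -> ImageVolume:
    """Read a user-supplied 2D TIFF/PNG image as an :class:`ImageVolume`.

    Raster formats carry no physical calibration, so the pixel size and the
    signal kind (``activity`` for tracer channels, ``hu`` for CT-calibrated
    exports) must be stated by the caller.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            grid = tifffile.imread(path)
        else:
            from PIL import Image

            grid = np.asarray(Image.open(path))
    except Exception as exc:
        raise FileFormatError(f"cannot read 2D image {path}: {exc}") from exc
    if grid.ndim == 3:  # RGB(A): average channels
        grid = grid[..., :3].mean(axis=-1)
    profile = ModalityProfile(
        name=f"external_{path.suffix.lstrip('.').lower()}",
        psf_fwhm=0.0,
        out_voxel_size=pixel_size_um,
        signal=signal,  # type: ignore[arg-type]
    )
    return ImageVolume(grid=grid.astype(float), voxel_size=pixel_size_um, modality=profile)


def write_sections_tiff(
    sections: list[PlaquePhantom], out_dir: PathLike, stem: str = "section"
) -> list[Path]:
    """Write 2D sections as 16-bit TIFF label images."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sec in enumerate(sections):
        grid = sec.grid
        if grid.ndim == 3:  # slabs thicker than one voxel: store max projection
            grid = grid.max(axis=0)
        p = out / f"{stem}_{i:03d}.tif"
        tifffile.imwrite(p, grid.astype(np.uint16))
        paths.append(p)
    return paths


def write_tac(tac: TimeActivityCurve, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"t_min": tac.times, "value": tac.values, "label": tac.label}
    ).to_csv(path, index=False)
    return path


def read_tac(path: PathLike) -> TimeActivityCurve:
    try:
        df = pd.read_csv(path)
        return TimeActivityCurve(
            times=df["t_min"].to_numpy(float),
            values=df["value"].to_numpy(float),
            label=str(df["label"].iloc[0]) if len(df) else "tissue",
        )
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"cannot parse TAC CSV {path}: {exc}") from exc


def write_dynamic_study(study: DynamicStudy, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame_start_s": study.frame_starts_s,
            "frame_end_s": study.frame_ends_s,
            "t_mid_min": study.t_mid_min,
            "plasma": study.plasma.values,
            "tissue": study.tissue.values,
        }
    ).to_csv(path, index=False)
    return path


def read_dynamic_study(
    path: PathLike,
) -> tuple[TimeActivityCurve, TimeActivityCurve, np.ndarray]:
    """Read a dynamic-study CSV back as (plasma, tissue, frame durations in min)."""
    try:
        df = pd.read_csv(path)
        t = df["t_mid_min"].to_numpy(float)
        durations = (df["frame_end_s"].to_numpy(float) - df["frame_start_s"].to_numpy(float)) / 60.0
        return (
            TimeActivityCurve(t, df["plasma"].to_numpy(float), "blood"),
            TimeActivityCurve(t, df["tissue"].to_numpy(float), "tissue"),
            durations,
        )
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"cannot parse dynamic study CSV {path}: {exc}") from exc


def write_tri_class(results: dict[str, TriClassResult], path: PathLike) -> Path:
    rows = []
    for pair, res in results.items():
        row = {"pair": pair}
        row.update({f"count_{k}": v for k, v in res.counts.items()})
        row.update({f"pct_{k}": v for k, v in res.percentages.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    return Path(path)


def read_tri_class(path: PathLike) -> dict[str, TriClassResult]:
    try:
        df = pd.read_csv(path)
        out = {}
        for _, row in df.iterrows():
            keys = ("pet_only", "both", "ct_only")
            out[str(row["pair"])] = TriClassResult(
                counts={k: int(row[f"count_{k}"]) for k in keys},
                percentages={k: float(row[f"pct_{k}"]) for k in keys},
            )
        return out
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"cannot parse tri-class CSV {path}: {exc}") from exc


def write_transect(profile: TransectProfile, path: PathLike) -> Path:
    pd.DataFrame(
        {
            "position_mm": profile.positions_mm,
            "pet": profile.pet_values,
            "ct_hu": profile.ct_values,
        }
    ).to_csv(Path(path), index=False)
    return Path(path)


def read_transect(path: PathLike) -> TransectProfile:
    try:
        df = pd.read_csv(path)
        return TransectProfile(
            positions_mm=df["position_mm"].to_numpy(float),
            pet_values=df["pet"].to_numpy(float),
            ct_values=df["ct_hu"].to_numpy(float),
        )
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"cannot parse transect CSV {path}: {exc}") from exc


def write_json_record(record: dict, path: PathLike) -> Path:
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True, default=float))
    return Path(path)


def read_json_record(path: PathLike) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"cannot parse JSON record {path}: {exc}") from exc
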