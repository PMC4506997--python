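"""End-to-end orchestration: phantom → uptake → modalities → quantification.

The central experiment mirrors the study's three-level comparison: the same
plaque, imaged as clinical PET/CT, μPET/μCT, and autoradiography/histology,
with the PET-positive-but-CT-negative fraction growing as resolution falls —
microcalcification signal without resolvable mineral.
"""

from __future__ import annotations

import logging
import time as _time
from pathlib import Path
from typing import Union

import numpy as np

from .adsorption import ActivityMap, KineticParameters, simulate_uptake
from .config import RunConfig, save_config
from .imaging import (
    MODALITY_PRESETS,
    ImageVolume,
    apply_modality,
    default_plasma_model,
    mineral_to_hu,
    plasma_curve,
    simulate_dynamic_study,
)
from .kinetics import (
    TimeActivityCurve,
    derive_kd,
    fit_association,
    fit_concentration_response,
    fit_dissociation,
    patlak,
)
from .phantom import PlaquePhantom, generate_phantom
from .quantification import (
    BinaryMask,
    TriClassResult,
    hu_calcification_mask,
    mask_pipeline,
    otsu_threshold,
    tri_class,
    upsample_mask,
)
from . import io as nafio

__all__ = ["run_end_to_end", "resolution_comparison", "kinetics_report"]

log = logging.getLogger("nafsim")

#: Stable sub-seed offsets so every stage draws from its own stream.
_STAGE_SEEDS = {"phantom": 0, "pet_noise": 1, "ct_noise": 2, "kinetics": 3}


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGE_SEEDS[stage]]).generate_state(1)[0] % (2**31))


def _pet_mask(image: ImageVolume, pair: str, blur_sigma: float) -> BinaryMask:
    """PET-positive delineation: Otsu for tomographic pairs, the full
    threshold→blur→re-threshold pipeline for the 2D autoradiography pair."""
    if pair == "autoradiography":
        return mask_pipeline(image, "otsu", blur_sigma, "li")
    t = otsu_threshold(image.grid)
    return BinaryMask(
        image.grid > t, image.voxel_size, provenance=f"otsu(t={t:.6g}) ({pair})"
    )


def _ct_mask(image: ImageVolume, pair: str, hu_threshold: float, blur_sigma: float) -> BinaryMask:
    """Mineral delineation: the ≥1,000 HU rule on CT; Otsu pipeline on the
    histology channel (a stain has no HU calibration)."""
    if pair == "histology":
        return mask_pipeline(image, "otsu", blur_sigma, "li")
    return hu_calcification_mask(image, hu_threshold)


def resolution_comparison(
    phantom: PlaquePhantom,
    activity: ActivityMap,
    hu_truth: ImageVolume,
    config: RunConfig,
    collect_images: bool = False,
) -> dict:
    """Render each modality pair and tabulate the tri-class partition.

    Masks from both modalities are upsampled to the phantom grid before
    comparison so that the partition is computed voxel-for-voxel on a common
    frame of reference.  Returns ``{pair_label: TriClassResult}`` (plus the
    rendered images when ``collect_images``).
    """
    seed = config.seed
    out: dict[str, TriClassResult] = {}
    images: dict[str, ImageVolume] = {}
    for pet_name, ct_name in config.imaging.pairs:
        pet_img = apply_modality(
            activity, MODALITY_PRESETS[pet_name], seed=_stage_seed(seed, "pet_noise")
        )
        ct_img = apply_modality(
            hu_truth, MODALITY_PRESETS[ct_name], seed=_stage_seed(seed, "ct_noise")
        )
        pet_mask = _pet_mask(pet_img, pet_name, config.quantification.blur_sigma_px)
        ct_mask = _ct_mask(
            ct_img, ct_name, config.quantification.hu_threshold,
            config.quantification.blur_sigma_px,
        )
        pet_up = upsample_mask(pet_mask, phantom.grid.shape, phantom.voxel_size)
        ct_up = upsample_mask(ct_mask, phantom.grid.shape, phantom.voxel_size)
        label = f"{pet_name}_vs_{ct_name}"
        out[label] = tri_class(pet_up, ct_up)
        if collect_images:
            images[label] = {"pet": pet_img, "ct": ct_img}
    return {"tri_class": out, "images": images} if collect_images else {"tri_class": out}


def kinetics_report(config: RunConfig) -> dict:
    """Fit the kinetic and dynamic models on curves generated from the
    configured constants; returns a JSON-serializable record."""
    kin = config.kinetics
    ads = config.adsorption
    params = KineticParameters(
        k_on=ads.k_on, k_off=ads.k_off, ligand_conc=ads.ligand_conc,
        site_density=ads.site_density,
    )

    from .adsorption import association_timecourse, dissociation_timecourse

    t_assoc = np.asarray(kin.association_times_min)
    assoc_tac = TimeActivityCurve(t_assoc, association_timecourse(params, t_assoc))
    assoc_fit = fit_association(assoc_tac, ads.ligand_conc, k_off_known=ads.k_off)

    t_wash = np.asarray(kin.wash_times_min)
    diss_tac = TimeActivityCurve(t_wash, dissociation_timecourse(params, 1.0, t_wash))
    diss_fit = fit_dissociation(diss_tac)

    kd_m = derive_kd(assoc_fit.k_on, diss_fit.k_off)

    lo, hi = kin.calibration_decades
    concs = 10.0 ** np.arange(lo, hi + 1, dtype=float)
    acts = 10.0 ** (kin.calibration_slope * np.log10(concs) + kin.calibration_intercept)
    calib = fit_concentration_response(concs, acts)

    plasma = default_plasma_model()
    study = simulate_dynamic_study(kin.patlak_ki, kin.patlak_v, plasma)
    pk = patlak(
        study.tissue, study.plasma, t_start=kin.patlak_t_start_min,
        frame_durations_min=study.frame_durations_min,
    )
    peak_tac = plasma_curve(plasma, np.linspace(0.0, 60.0, 601))
    ratio_60 = float(peak_tac.values[-1] / peak_tac.values.max())

    return {
        "association": {
            "k_obs_per_min": assoc_fit.k_obs,
            "k_on_per_M_per_min": assoc_fit.k_on,
            "half_time_min": assoc_fit.half_time_assoc,
        },
        "dissociation": {
            "k_off_per_min": diss_fit.k_off,
            "half_time_min": diss_fit.half_time_dissoc,
        },
        "kd": {"molar": kd_m, "picomolar": kd_m * 1e12},
        "calibration": {
            "slope": calib.slope,
            "intercept": calib.intercept,
            "r_squared": calib.r_squared,
        },
        "patlak": {
            "ki_ml_cm3_min": pk.ki,
            "v": pk.v,
            "r_squared": pk.r_squared,
            "true_ki": kin.patlak_ki,
            "true_v": kin.patlak_v,
        },
        "plasma_fraction_at_60min": ratio_60,
    }


def run_end_to_end(config: RunConfig, out_dir: Union[str, Path]) -> dict:
    """Run the full pipeline, writing every intermediate to ``out_dir``.

    Deterministic for fixed (config, seed): all randomness derives from the
    single master seed through named per-stage streams.  Errors from any
    stage propagate annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config_echo.yaml")
    bundle: dict = {}

    def stage(name: str):
        log.info("stage %s", name)
        return _StageTimer(name)

    try:
        with stage("phantom"):
            phantom = generate_phantom(
                config.phantom.to_phantom_config(), seed=_stage_seed(config.seed, "phantom")
            )
            nafio.write_phantom(phantom, out, "phantom")
            bundle["phantom"] = phantom

        with stage("adsorption"):
            ads = config.adsorption
            params = KineticParameters(
                k_on=ads.k_on, k_off=ads.k_off, ligand_conc=ads.ligand_conc,
                site_density=ads.site_density,
            )
            activity = simulate_uptake(
                phantom, params,
                incubation_time=ads.incubation_time_min,
                penetration_depth=ads.penetration_depth_um,
                sectioned_first=ads.sectioned_first,
                saturable=ads.saturable,
            )
            nafio.write_activity_map(activity, out / "activity.nii")
            bundle["activity"] = activity

        with stage("imaging"):
            hu_truth = mineral_to_hu(
                phantom, config.imaging.hu_bg, config.imaging.hu_soft,
                config.imaging.hu_calc,
            )
            bundle["hu_truth"] = hu_truth

        with stage("quantification"):
            comp = resolution_comparison(
                phantom, activity, hu_truth, config, collect_images=True
            )
            bundle["tri_class"] = comp["tri_class"]
            for label, pair_imgs in comp["images"].items():
                nafio.write_image(pair_imgs["pet"], out / f"{label}_pet.nii")
                nafio.write_image(pair_imgs["ct"], out / f"{label}_ct.nii")
            nafio.write_tri_class(comp["tri_class"], out / "tri_class.csv")

        with stage("kinetics"):
            report = kinetics_report(config)
            bundle["kinetics"] = report
            nafio.write_json_record(report, out / "kinetics.json")

        with stage("summary"):
            summary = {
                "seed": config.seed,
                "n_deposits": len(phantom.deposits),
                "pet_only_pct": {
                    k: v.percentages["pet_only"] for k, v in bundle["tri_class"].items()
                },
                "kd_pm": report["kd"]["picomolar"],
                "patlak_ki": report["patlak"]["ki_ml_cm3_min"],
            }
            nafio.write_json_record(summary, out / "summary.json")
            bundle["summary"] = summary
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {_StageTimer.last_stage!r} "
            f"(seed={config.seed}): {exc}"
        ) from exc
    return bundle


class _StageTimer:
    last_stage: str = "<none>"

    def __init__(self, name: str) -> None:
        self.name = name
        _StageTimer.last_stage = name

    def __enter__(self):
        self.t0 = _time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = _time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s finished in %.2f s", self.name, dt)
        else:
            log.error("stage %s failed after %.2f s: %s", self.name, dt, exc)
        return False
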