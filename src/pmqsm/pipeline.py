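"""Full pipeline orchestration: raw multi-coil echoes to χ/R2* maps.

Stage order per repeat: echo alignment → coil combination → readout
phase-gradient removal → mask generation → unwrapping/initialization →
nonlinear field fit → φ0 mask refinement.  Across repeats: translation
alignment → field averaging (with drift diagnostics) → v-SHARP background
removal → dipole inversion → whole-brain referencing.  In parallel the
repeat-aligned, repeat-averaged magnitudes feed the R2* fit and the T2*
drift report.  ``process_brain`` is the in-memory core (a pure function of
its inputs); ``run_pipeline`` adds file I/O and provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nifti_io
from .combine import (align_echoes_first_to_rest, align_repeats,
                      combine_coils, truncate_kspace_slice)
from .fieldmap import (BrainMask, average_repeat_fields, fit_field_nonlinear,
                       generate_mask, refine_mask_phi0,
                       remove_readout_phase_gradient)
from .params import AcquisitionParams, PhantomSpec, load_config
from .phantom import (MultiCoilEchoData, build_phantom, simulate_acquisition,
                      translate_fourier)
from .qsm import (make_dipole_kernel, reference_susceptibility,
                  streak_reduced_inversion, tkd_inversion,
                  vsharp_background_removal)
from .r2star import assess_t2star_drift, fit_r2star

log = logging.getLogger("pmqsm")


@dataclass
class PipelineConfig:
    params: AcquisitionParams
    mask_threshold_frac: float = 0.1
    phi0_threshold_rad: float = 1.0
    fit_max_iter: int = 50
    fit_tol: float = 1e-10
    vsharp_max_kernel_mm: float = 12.0
    vsharp_reg_param: float = 0.02
    inversion_method: str = "star"  # "star" | "tkd"
    tkd_threshold: float = 0.2
    truncate_slice_factor: int = 1
    remove_readout_gradient: bool = True
    per_repeat_drift: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["params"] = self.params.to_dict()
        return d


def process_brain(data: MultiCoilEchoData, config: PipelineConfig) -> dict:
    """Run every processing stage in memory; returns a dict of artifacts.

    Keys: ``chi`` (referenced SusceptibilityMap), ``r2star``
    (R2StarFitResult), ``field`` (averaged FieldMapResult), ``local_field``,
    ``drift_diag`` (field-level), ``t2s_drift`` (DriftReport or None),
    ``mask``, ``echo_shifts``, ``repeat_shifts``.
    """
    t0 = time.time()
    if config.truncate_slice_factor > 1:
        log.info("k-space slice truncation x%d", config.truncate_slice_factor)
        data = truncate_kspace_slice(data, config.truncate_slice_factor)
    params = data.params

    series_list, field_list, echo_shift_log = [], [], []
    for r in range(data.n_repeats):
        log.info("repeat %d: echo alignment", r + 1)
        shifts, aligned_first = align_echoes_first_to_rest(data, r)
        echo_shift_log.append(shifts)
        log.info("repeat %d: coil combination", r + 1)
        series = combine_coils(data, r, aligned_first=aligned_first)
        log.info("repeat %d: mask generation", r + 1)
        mask = generate_mask(series.magnitude[0], config.mask_threshold_frac)
        if config.remove_readout_gradient:
            log.info("repeat %d: readout phase-gradient removal", r + 1)
            series = remove_readout_phase_gradient(series, mask)
        log.info("repeat %d: field fit", r + 1)
        result = fit_field_nonlinear(series, mask, max_iter=config.fit_max_iter,
                                     tol=config.fit_tol)
        refined = refine_mask_phi0(result, config.phi0_threshold_rad)
        result.mask = refined
        series_list.append(series)
        field_list.append(result)

    log.info("repeat alignment")
    repeat_shifts, aligned_series = align_repeats(series_list)
    for res, shift in zip(field_list, repeat_shifts):
        if np.any(shift != 0):
            res.delta_f_Hz = translate_fourier(res.delta_f_Hz, shift)
            res.rms_residual = translate_fourier(res.rms_residual, shift)
            res.mask = BrainMask(
                volume=translate_fourier(res.mask.volume.astype(float), shift) > 0.5,
                provenance=res.mask.provenance)

    log.info("field averaging")
    avg_field, drift_diag = average_repeat_fields(field_list)
    mask = avg_field.mask

    log.info("v-SHARP background removal")
    local_field, eroded = vsharp_background_removal(
        avg_field.delta_f_Hz, mask.volume, params.voxel_size_mm,
        config.vsharp_max_kernel_mm, config.vsharp_reg_param)
    eroded_mask = BrainMask(volume=eroded, provenance="vsharp-eroded")

    log.info("dipole inversion (%s)", config.inversion_method)
    kernel = make_dipole_kernel(local_field.shape, params.voxel_size_mm,
                                params.b0_direction)
    if config.inversion_method == "tkd":
        chi = tkd_inversion(local_field, kernel, params, eroded,
                            threshold=config.tkd_threshold)
    elif config.inversion_method == "star":
        chi = streak_reduced_inversion(local_field, kernel, params, eroded)
    else:
        raise ValueError(f"unknown inversion method {config.inversion_method!r}")
    log.info("whole-brain referencing")
    chi = reference_susceptibility(chi)

    log.info("R2* mapping")
    avg_mag = np.mean(np.stack([s.magnitude for s in aligned_series]), axis=0)
    r2s = fit_r2star(avg_mag, params, mask)
    t2s_drift = None
    if config.per_repeat_drift and data.n_repeats >= 2:
        log.info("T2* drift assessment")
        t2s_drift = assess_t2star_drift(
            np.stack([s.magnitude for s in aligned_series]), params, mask)

    log.info("pipeline done in %.1f s", time.time() - t0)
    return {"chi": chi, "r2star": r2s, "field": avg_field,
            "local_field": local_field, "eroded_mask": eroded_mask,
            "drift_diag": drift_diag, "t2s_drift": t2s_drift, "mask": mask,
            "echo_shifts": np.asarray(echo_shift_log),
            "repeat_shifts": repeat_shifts}


def run_pipeline(config: PipelineConfig, data: MultiCoilEchoData | None = None,
                 in_dir=None, out_dir="pmqsm_out", keep_intermediates=True) -> Path:
    """File-level wrapper: load (or accept) data, process, write artifacts
    plus a JSON provenance sidecar.  Returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        if in_dir is None:
            raise ValueError("either data or in_dir is required")
        data = nifti_io.load_acquisition(in_dir, config.params)
    res = process_brain(data, config)
    vox = data.params.voxel_size_mm
    if config.truncate_slice_factor > 1:
        v = list(vox)
        v[data.params.slice_axis] *= config.truncate_slice_factor
        vox = tuple(v)
    nifti_io.save_volume(res["chi"].chi_ppb, out / "chi_ppb.nii.gz", vox,
                         description=res["chi"].method)
    nifti_io.save_volume(res["r2star"].r2star_per_s, out / "r2star_s-1.nii.gz", vox)
    nifti_io.save_volume(res["r2star"].m0, out / "m0.nii.gz", vox)
    nifti_io.save_volume(res["r2star"].noise_floor, out / "noise.nii.gz", vox)
    nifti_io.save_volume(res["mask"].volume.astype(float), out / "mask.nii.gz", vox)
    if keep_intermediates:
        nifti_io.save_volume(res["field"].delta_f_Hz, out / "delta_f_Hz.nii.gz", vox)
        nifti_io.save_volume(res["local_field"], out / "local_field_Hz.nii.gz", vox)
        nifti_io.save_volume(res["eroded_mask"].volume.astype(float),
                             out / "mask_eroded.nii.gz", vox)
    res["drift_diag"].to_frame().to_csv(out / "drift_diagnostics.csv", index=False)
    if res["t2s_drift"] is not None:
        res["t2s_drift"].to_frame().to_csv(out / "t2star_drift.csv", index=False)
    import pandas as pd
    pd.DataFrame(res["echo_shifts"],
                 columns=[f"echo{n + 2}" for n in
                          range(res["echo_shifts"].shape[1])]).to_csv(
        out / "echo_pe_shifts_voxels.csv", index=False)
    pd.DataFrame(res["repeat_shifts"], columns=["x", "y", "z"]).to_csv(
        out / "repeat_shifts_voxels.csv", index=False)
    import pmqsm
    prov = {"config": config.to_dict(), "version": pmqsm.__version__,
            "seed": config.seed}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return out


def simulate_to_dir(phantom_cfg: dict, out_dir) -> Path:
    """Build a phantom from a config dict, simulate, and write NIfTI files
    plus the ground truth."""
    spec = PhantomSpec.from_dict(phantom_cfg["phantom"])
    params = AcquisitionParams.from_dict(phantom_cfg["acquisition"])
    truth = build_phantom(spec, voxel_size_mm=params.voxel_size_mm)
    data = simulate_acquisition(truth, spec, params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nifti_io.save_acquisition(data, out)
    vox = params.voxel_size_mm
    nifti_io.save_volume(truth.chi_ppb, out / "truth_chi_ppb.nii.gz", vox)
    nifti_io.save_volume(truth.r2s_per_s, out / "truth_r2star_s-1.nii.gz", vox)
    nifti_io.save_volume(truth.m0, out / "truth_m0.nii.gz", vox)
    nifti_io.save_volume(truth.labels.astype(float), out / "truth_labels.nii.gz", vox)
    return out
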