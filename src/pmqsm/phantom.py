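"""Synthetic phantom construction and forward GRE acquisition simulation.

The phantom reproduces the features of a whole post-mortem brain scanned in
a susceptibility-matched, signal-free immersion liquid: piecewise-constant
χ/R2*/M0 per tissue, a cortical-ribbon patch of elevated susceptibility, and
air bubbles as strong dipole sources.  The forward simulation then applies
the acquisition physics the pipeline must undo — per-coil complex
sensitivities with constant phase offsets, linear phase evolution from the
dipole field, per-repeat B0 drift, per-echo phase-encode translations, and
additive complex Gaussian noise (magnitudes therefore become Rician).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import AcquisitionParams, PhantomSpec
from .qsm import make_dipole_kernel

TISSUE_LABELS = {"surround": 0, "white": 1, "grey": 2, "ribbon": 3}


@dataclass
class GroundTruth:
    """Voxel-wise ground truth of the phantom (recovery target)."""

    chi_ppb: np.ndarray
    r2s_per_s: np.ndarray
    m0: np.ndarray
    labels: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.chi_ppb)):
            raise ValueError("chi must be finite everywhere")


@dataclass
class MultiCoilEchoData:
    """Complex volumes indexed (repeat, coil, echo, x, y, z)."""

    data: np.ndarray
    params: AcquisitionParams

    def __post_init__(self):
        if self.data.ndim != 6:
            raise ValueError("expected 6-D (repeat, coil, echo, x, y, z)")
        if self.data.shape[2] != self.params.n_echoes:
            raise ValueError("echo count does not match params")

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]


def _coordinate_grids_mm(shape, voxel_size_mm):
    """Physical coordinates (mm) centered on the grid center."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * dx
            for n, dx in zip(shape, voxel_size_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def build_phantom(spec: PhantomSpec,
                  voxel_size_mm=(1.0, 1.0, 1.0)) -> GroundTruth:
    """Rasterize the phantom geometry into piecewise-constant maps.

    Bubbles overwrite χ with their value (given in ppm, stored in ppb) and
    zero out M0 — air carries no signal.  Deterministic: geometry is purely
    analytic, no randomness enters here.
    """
    shape = tuple(spec.grid_shape)
    X, Y, Z = _coordinate_grids_mm(shape, voxel_size_mm)
    a, b, c = (float(v) for v in spec.brain_semi_axes_mm)
    ell = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2
    brain = ell <= 1.0
    wf = spec.white_fraction
    white = ell <= wf**2
    grey = brain & ~white

    labels = np.zeros(shape, dtype=np.int8)
    labels[white] = TISSUE_LABELS["white"]
    labels[grey] = TISSUE_LABELS["grey"]

    rib = spec.ribbon_region
    if "direction" in rib:
        d = np.asarray(rib["direction"], dtype=float)
        d = d / np.linalg.norm(d)
        r = np.sqrt(X**2 + Y**2 + Z**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (X * d[0] + Y * d[1] + Z * d[2]) / np.where(r > 0, r, np.inf)
        ribbon = grey & (cosang >= np.cos(np.deg2rad(rib["half_angle_deg"])))
    elif "center_mm" in rib:
        cx, cy, cz = rib["center_mm"]
        sphere = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
                  <= rib["radius_mm"] ** 2)
        if sphere.any() and not (sphere & grey).any():
            raise ValueError("ribbon region lies outside grey matter")
        ribbon = sphere & grey
    else:
        raise ValueError("ribbon_region needs 'direction' or 'center_mm'")
    if not ribbon.any():
        raise ValueError("ribbon region is empty")
    labels[ribbon] = TISSUE_LABELS["ribbon"]

    chi = np.zeros(shape)
    r2s = np.zeros(shape)
    m0 = np.zeros(shape)
    for name, lab in TISSUE_LABELS.items():
        sel = labels == lab
        chi[sel] = spec.tissue_chi_ppb[name]
        r2s[sel] = spec.tissue_r2s_per_s[name]
        m0[sel] = spec.tissue_m0[name]

    for bub in spec.bubbles:
        bx, by, bz = bub["center_mm"]
        inside = ((X - bx) ** 2 + (Y - by) ** 2 + (Z - bz) ** 2
                  <= bub["radius_mm"] ** 2)
        chi[inside] = bub["chi_ppm"] * 1000.0
        m0[inside] = 0.0
        r2s[inside] = 0.0

    return GroundTruth(chi_ppb=chi, r2s_per_s=r2s, m0=m0, labels=labels,
                       brain_mask=brain)


def forward_dipole_field(chi_ppb: np.ndarray, params: AcquisitionParams,
                         pad_factor: int = 2) -> np.ndarray:
    """Frequency-offset map (Hz) induced by a susceptibility distribution.

    Δf = f0 · IFT{ D(k) · FT{χ} } with the unit dipole response
    D(k) = 1/3 − (k·b̂)²/|k|² and D(0) := 0.  The convolution is periodic;
    zero-padding by ``pad_factor`` (default 2) suppresses wrap-around from
    the domain boundaries.
    """
    chi_ppb = np.asarray(chi_ppb, dtype=float)
    if not np.all(np.isfinite(chi_ppb)):
        raise ValueError("chi must be finite")
    shape = chi_ppb.shape
    if pad_factor > 1:
        pshape = tuple(int(n * pad_factor) for n in shape)
        padded = np.zeros(pshape)
        sl = tuple(slice(0, n) for n in shape)
        padded[sl] = chi_ppb
    else:
        pshape, padded, sl = shape, chi_ppb, tuple(slice(0, n) for n in shape)
    kernel = make_dipole_kernel(pshape, params.voxel_size_mm,
                                params.b0_direction)
    field = np.fft.ifftn(np.fft.fftn(padded) * kernel.values).real
    return field[sl] * params.hz_per_ppb


def _coil_sensitivities(shape, n_coils, phase_offsets_rad, voxel_size_mm):
    """Smooth complex coil profiles: Gaussian magnitude centered outside the
    volume on a ring, linear phase ramp, plus the constant per-coil offset."""
    X, Y, Z = _coordinate_grids_mm(shape, voxel_size_mm)
    fov = max(n * d for n, d in zip(shape, voxel_size_mm))
    sens = np.empty((n_coils,) + tuple(shape), dtype=complex)
    for c in range(n_coils):
        if n_coils == 1:
            mag = np.ones(shape)
            ramp = np.zeros(shape)
        else:
            ang = 2 * np.pi * c / n_coils
            cx, cy = 0.7 * fov * np.cos(ang), 0.7 * fov * np.sin(ang)
            d2 = (X - cx) ** 2 + (Y - cy) ** 2 + Z**2
            mag = np.exp(-d2 / (2 * (0.8 * fov) ** 2))
            ramp = 0.02 * (np.cos(ang) * X + np.sin(ang) * Y) + 0 * Z
        sens[c] = mag * np.exp(1j * (ramp + phase_offsets_rad[c]))
    return sens


def translate_fourier(volume: np.ndarray, shift_voxels, axes=None) -> np.ndarray:
    """Subvoxel translation via Fourier phase ramp (periodic boundaries)."""
    vol = np.asarray(volume)
    complex_in = np.iscomplexobj(vol)
    if axes is None:
        axes = range(vol.ndim)
    fk = np.fft.fftn(vol, axes=tuple(axes))
    for ax, s in zip(axes, np.atleast_1d(shift_voxels)):
        if s == 0:
            continue
        k = np.fft.fftfreq(vol.shape[ax])
        ramp = np.exp(-2j * np.pi * k * s)
        sh = [1] * vol.ndim
        sh[ax] = vol.shape[ax]
        fk = fk * ramp.reshape(sh)
    out = np.fft.ifftn(fk, axes=tuple(axes))
    return out if complex_in else out.real


def simulate_acquisition(truth: GroundTruth, spec: PhantomSpec,
                         params: AcquisitionParams) -> MultiCoilEchoData:
    """Forward-simulate the multi-coil, multi-echo, multi-repeat GRE signal.

    Per coil c, echo n, repeat r:
        S = C_c(r⃗)·M0·e^(−TEₙ·R2*)·e^(i[φ0_c + 2π(Δf + drift_r)·TEₙ]) + ε,
    with ε complex Gaussian, then each echo translated along the
    phase-encode axis by ``echo_pe_shift_voxels[n]`` (drift-induced
    misalignment grows with echo time in the real acquisition; here the
    shifts are prescribed).
    """
    if params.n_echoes < 1:
        raise ValueError("echo time list is empty")
    spec.validate_repeats(params.n_repeats)
    if len(spec.echo_pe_shift_voxels) < params.n_echoes:
        raise ValueError("need one PE shift per echo")
    rng = np.random.default_rng(spec.seed)
    shape = truth.chi_ppb.shape
    delta_f = forward_dipole_field(truth.chi_ppb, params)
    sens = _coil_sensitivities(shape, spec.n_coils,
                               spec.coil_phase_offsets_rad,
                               params.voxel_size_mm)
    te_s = np.asarray(params.echo_times_ms) * 1e-3
    data = np.empty((params.n_repeats, spec.n_coils, params.n_echoes) + shape,
                    dtype=complex)
    decay = truth.m0[None] * np.exp(-te_s[:, None, None, None]
                                    * truth.r2s_per_s[None])
    for r in range(params.n_repeats):
        freq = delta_f + spec.repeat_drift_Hz[r]
        for n in range(params.n_echoes):
            phase = 2 * np.pi * freq * te_s[n]
            base = decay[n] * np.exp(1j * phase)
            for c in range(spec.n_coils):
                sig = sens[c] * base
                if spec.echo_pe_shift_voxels[n] != 0:
                    sig = translate_fourier(sig, [spec.echo_pe_shift_voxels[n]],
                                            axes=[params.phase_encode_axis])
                if spec.noise_sigma > 0:
                    sig = sig + spec.noise_sigma * (
                        rng.standard_normal(shape)
                        + 1j * rng.standard_normal(shape))
                data[r, c, n] = sig
    return MultiCoilEchoData(data=data, params=params)
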