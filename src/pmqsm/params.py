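"""Acquisition and phantom parameter types.

All physical quantities carry explicit units in their field names.  The
acquisition geometry distinguishes three scanner axes (readout, phase-encode,
slice) because artefact corrections downstream are constrained to specific
axes: echo-to-echo misalignment is a pure phase-encode translation, readout
phase gradients are fitted along the readout axis only, and k-space
truncation acts along the slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: Protocol echo times (ms) of the 7 T post-mortem multi-echo GRE acquisition.
DEFAULT_ECHO_TIMES_MS = (2.0, 8.6, 15.2, 21.8, 28.4, 35.0)


@dataclass
class AcquisitionParams:
    """Multi-echo GRE acquisition geometry and timing.

    Parameters
    ----------
    echo_times_ms
        Strictly increasing echo times in milliseconds.
    field_strength_T
        Main magnetic field B0 in Tesla.
    gamma_MHz_per_T
        Gyromagnetic ratio over 2π (proton: 42.577 MHz/T).
    voxel_size_mm
        Voxel edge lengths (mm) along the three array axes.
    b0_direction
        Unit vector of the main field in array coordinates.
    readout_axis, phase_encode_axis, slice_axis
        Array axis indices (a permutation of 0, 1, 2).
    n_repeats
        Number of repeated acquisitions.
    """

    echo_times_ms: tuple = DEFAULT_ECHO_TIMES_MS
    field_strength_T: float = 7.0
    gamma_MHz_per_T: float = 42.577
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    b0_direction: tuple = (0.0, 0.0, 1.0)
    readout_axis: int = 0
    phase_encode_axis: int = 1
    slice_axis: int = 2
    n_repeats: int = 4

    def __post_init__(self):
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.ndim != 1 or te.size < 1 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        b0 = np.asarray(self.b0_direction, dtype=float)
        if abs(np.linalg.norm(b0) - 1.0) > 1e-9:
            raise ValueError("b0_direction must be a unit vector")
        axes = {self.readout_axis, self.phase_encode_axis, self.slice_axis}
        if axes != {0, 1, 2}:
            raise ValueError("readout/phase-encode/slice axes must be a permutation of {0,1,2}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        if np.any(np.asarray(self.voxel_size_mm, dtype=float) <= 0):
            raise ValueError("voxel sizes must be positive")
        self.echo_times_ms = tuple(float(t) for t in te)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.b0_direction = tuple(float(v) for v in b0)

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def effective_echo_times_ms(self) -> np.ndarray:
        """TE'_n = TE_n − TE_1 for n ≥ 2 — the time base after first-echo
        phase subtraction (one fewer entry than the echo count)."""
        te = np.asarray(self.echo_times_ms)
        return te[1:] - te[0]

    @property
    def larmor_frequency_Hz(self) -> float:
        return self.gamma_MHz_per_T * 1e6 * self.field_strength_T

    @property
    def hz_per_ppb(self) -> float:
        """Frequency offset (Hz) produced by unit dipole response to 1 ppb."""
        return self.larmor_frequency_Hz * 1e-9

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)


def aliasing_threshold_Hz(echo_spacing_ms: float = 6.6) -> float:
    """Frequency offset that accrues π of phase per echo spacing.

    Above this offset the per-echo phase increment wraps, so a field fit
    without spatial-unwrapping-based initialization can alias by a multiple
    of 1/ΔTE.  For the 6.6 ms effective spacing this is ≈ 75.76 s⁻¹.
    """
    return np.pi / (2 * np.pi * echo_spacing_ms * 1e-3)


def readout_snr_gain(bw_actual_Hz_per_px: float = 650.0,
                     bw_minimal_Hz_per_px: float = 210.0) -> float:
    """SNR gain available by lowering the readout bandwidth.

    SNR scales with 1/√bandwidth; dropping 650 Hz/px to 210 Hz/px for the
    later echoes (which have dead time to spare) gains √(650/210) ≈ 1.76×.
    """
    return float(np.sqrt(bw_actual_Hz_per_px / bw_minimal_Hz_per_px))


@dataclass
class PhantomSpec:
    """Geometry, tissue properties and artefact settings of the synthetic
    phantom.

    The phantom emulates a whole post-mortem brain immersed in a
    susceptibility-matched, signal-free perfluorocarbon liquid inside a
    spherical container: an ellipsoidal "brain" with a white-matter core, a
    grey-matter shell, a cortical-ribbon patch of elevated susceptibility
    (the simulated motor-cortex hyperintensity), and optional air bubbles.

    Tissue susceptibilities/R2* for fixed post-mortem tissue are not pinned
    down by literature consensus; the defaults are plausible round numbers
    and every one is config-exposed.
    """

    grid_shape: tuple = (64, 64, 64)
    container_radius_mm: float = 28.0
    brain_semi_axes_mm: tuple = (22.0, 18.0, 16.0)
    white_fraction: float = 0.75  # inner ellipsoid scale separating white core from grey shell
    tissue_chi_ppb: dict = field(default_factory=lambda: {
        "surround": 0.0, "white": -30.0, "grey": 20.0, "ribbon": 50.0})
    tissue_r2s_per_s: dict = field(default_factory=lambda: {
        "surround": 1.0, "white": 45.0, "grey": 35.0, "ribbon": 50.0})
    tissue_m0: dict = field(default_factory=lambda: {
        "surround": 0.0, "white": 1000.0, "grey": 800.0, "ribbon": 800.0})
    # cortical-ribbon patch: cap of the grey shell around `direction`, or an
    # explicit sphere {"center_mm": [...], "radius_mm": r}
    ribbon_region: dict = field(default_factory=lambda: {
        "direction": (0.0, 1.0, 0.0), "half_angle_deg": 35.0})
    bubbles: list = field(default_factory=list)  # dicts: center_mm, radius_mm, chi_ppm
    n_coils: int = 1
    coil_phase_offsets_rad: tuple = (0.0,)
    noise_sigma: float = 0.0
    repeat_drift_Hz: tuple = (0.0,)
    echo_pe_shift_voxels: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.container_radius_mm <= 0:
            raise ValueError("container radius must be positive")
        if np.any(np.asarray(self.brain_semi_axes_mm, dtype=float) <= 0):
            raise ValueError("degenerate brain ellipsoid (zero-volume)")
        if not 0 < self.white_fraction < 1:
            raise ValueError("white_fraction must be in (0, 1)")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if len(self.coil_phase_offsets_rad) != self.n_coils:
            raise ValueError("one phase offset per coil required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for b in self.bubbles:
            if b["radius_mm"] <= 0:
                raise ValueError("bubble radius must be positive")
            c = np.asarray(b["center_mm"], dtype=float)
            if np.linalg.norm(c) + b["radius_mm"] > self.container_radius_mm:
                raise ValueError("bubble lies outside the container")

    def validate_repeats(self, n_repeats: int) -> None:
        if len(self.repeat_drift_Hz) != n_repeats:
            raise ValueError("len(repeat_drift_Hz) must equal n_repeats")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


def _tupleize(obj):
    if isinstance(obj, dict):
        return {k: _tupleize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tupleize(v) for v in obj]
    return obj


def load_config(path) -> dict:
    """Load a YAML/JSON config file into a plain dict (keys as field names)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(d: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_tupleize(d), fh, sort_keys=False)
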