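"""Coil combination, echo/repeat alignment and k-space slice truncation.

The per-channel phase offset φ0_c(r⃗) (coil sensitivity phase plus any
constant instrumental offset) is removed by subtracting the first-echo
phase of the same channel, producing offset-free phase-difference images at
effective echo times TE'_n = TE_n − TE_1.  Because the offset is
time-independent this cancellation is exact.  The offset-corrected channels
are then combined by a (magnitude-weighted) complex sum; magnitudes are
combined root-sum-of-squares over coils for all echoes.

B0 drift translates images along the phase-encode axis by an amount that
grows with echo time, so before the subtraction the *first* echo is
registered to each later echo (never the reverse — the later echoes, which
feed all downstream stages, are never interpolated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .params import AcquisitionParams
from .phantom import MultiCoilEchoData, translate_fourier


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    return np.pi - np.mod(np.pi - phi, 2 * np.pi)


@dataclass
class CombinedEchoSeries:
    """Coil-combined magnitude (all echoes) and offset-free phase
    (effective echoes, wrapped to (−π, π])."""

    magnitude: np.ndarray        # (n_echoes, x, y, z)
    phase: np.ndarray            # (n_echoes − 1, x, y, z)
    effective_echo_times_ms: np.ndarray
    params: AcquisitionParams
    repeat: int = 0
    flagged: np.ndarray | None = None  # voxels with zero first-echo signal

    def __post_init__(self):
        if self.phase.shape[0] != self.magnitude.shape[0] - 1:
            raise ValueError("need one fewer phase image than magnitude images")
        eff = np.asarray(self.effective_echo_times_ms, dtype=float)
        if np.any(eff <= 0) or np.any(np.diff(eff) <= 0):
            raise ValueError("effective echo times must be positive increasing")
        self.effective_echo_times_ms = eff

    @property
    def complex_phase(self) -> np.ndarray:
        return np.exp(1j * self.phase)


def truncate_kspace_slice(data: MultiCoilEchoData, factor: int) -> MultiCoilEchoData:
    """Center-crop k-space along the slice axis to downsample resolution.

    Keeps the central ``ceil(n/factor)`` band of k-space; the voxel size
    along the slice axis grows by ``factor``.  Values of band-limited
    inputs are preserved (amplitudes rescaled for the shorter transform).
    """
    if factor < 1:
        raise ValueError("truncation factor must be >= 1")
    ax = data.params.slice_axis
    n = data.data.shape[3 + ax]
    if factor >= n:
        raise ValueError("truncation factor must be smaller than the slice count")
    n_out = int(np.ceil(n / factor))
    full_ax = 3 + ax
    fk = np.fft.fftshift(np.fft.fft(data.data, axis=full_ax), axes=full_ax)
    start = (n - n_out) // 2
    sl = [slice(None)] * data.data.ndim
    sl[full_ax] = slice(start, start + n_out)
    fk = fk[tuple(sl)]
    out = np.fft.ifft(np.fft.ifftshift(fk, axes=full_ax), axis=full_ax)
    out = out * (n_out / n)
    vox = list(data.params.voxel_size_mm)
    vox[ax] = vox[ax] * factor
    new_params = AcquisitionParams(**{**data.params.to_dict(),
                                      "voxel_size_mm": tuple(vox)})
    return MultiCoilEchoData(data=out, params=new_params)


def sum_of_squares_magnitude(data: MultiCoilEchoData, repeat: int) -> np.ndarray:
    """Root-sum-of-squares magnitude over coils, per echo."""
    return np.sqrt((np.abs(data.data[repeat]) ** 2).sum(axis=0))


def align_echoes_first_to_rest(data: MultiCoilEchoData, repeat: int,
                               upsample_factor: int = 50):
    """Estimate the per-echo phase-encode translation of each later echo
    relative to the first and resample the first echo into each later
    echo's frame.

    Returns ``(shifts, aligned_first)`` where ``shifts[n]`` is the scalar
    PE-axis displacement of echo n+1 relative to echo 0 (voxels) and
    ``aligned_first[c, n]`` is coil c's first echo translated into echo
    n+1's frame.  The estimate uses subpixel Fourier cross-correlation of
    the sum-of-squares magnitudes, with only the phase-encode component
    retained (the drift mechanism cannot translate along other axes).
    """
    params = data.params
    pe = params.phase_encode_axis
    mags = sum_of_squares_magnitude(data, repeat)
    n_echoes = mags.shape[0]
    ref0 = mags[0]
    if np.ptp(ref0) == 0:
        import warnings
        warnings.warn("featureless magnitude images; assuming zero shift")
        shifts = np.zeros(n_echoes - 1)
    else:
        shifts = np.empty(n_echoes - 1)
        for n in range(1, n_echoes):
            # shift that maps the first echo onto echo n
            shift3, _, _ = phase_cross_correlation(
                mags[n], ref0, upsample_factor=upsample_factor,
                normalization=None)
            shifts[n - 1] = shift3[pe]
    aligned_first = np.empty((data.n_coils, n_echoes - 1) + mags.shape[1:],
                             dtype=complex)
    for c in range(data.n_coils):
        for n in range(n_echoes - 1):
            aligned_first[c, n] = translate_fourier(
                data.data[repeat, c, 0], [shifts[n]], axes=[pe])
    return shifts, aligned_first


def combine_coils(data: MultiCoilEchoData, repeat: int,
                  aligned_first: np.ndarray | None = None,
                  weighted: bool = True) -> CombinedEchoSeries:
    """Remove per-coil phase offsets by first-echo subtraction, then
    combine coils.

    For coil c and later echo n the offset-free phase term is
    e^{iΔφ_c} = S_c(TE_n)·conj(S_c(TE_1)) / (|S_c(TE_n)||S_c(TE_1)|); the
    combined phase is the argument of Σ_c w_c·e^{iΔφ_c} with
    w_c = |S_c(TE_1)| (magnitude-weighted, default) or w_c = 1.  Voxels
    where a coil has zero first-echo signal are flagged (their term is
    dropped, never NaN).  Magnitude is root-sum-of-squares per echo.
    """
    vols = data.data[repeat]  # (coil, echo, x, y, z)
    n_coils, n_echoes = vols.shape[:2]
    if aligned_first is None:
        first = np.broadcast_to(vols[:, :1], (n_coils, n_echoes - 1)
                                + vols.shape[2:])
    else:
        first = aligned_first
    later = vols[:, 1:]
    mag_later = np.abs(later)
    mag_first = np.abs(first)
    flagged = np.any(mag_first == 0, axis=(0, 1)) | np.any(mag_later == 0, axis=(0, 1))
    denom = mag_later * mag_first
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(denom > 0, later * np.conj(first) / denom, 0.0)
    weights = mag_first if weighted else (denom > 0).astype(float)
    combined = (weights * unit).sum(axis=0)  # (echo-1, x, y, z)
    phase = wrap_phase(np.angle(combined))
    magnitude = sum_of_squares_magnitude(data, repeat)
    return CombinedEchoSeries(
        magnitude=magnitude, phase=phase,
        effective_echo_times_ms=data.params.effective_echo_times_ms,
        params=data.params, repeat=repeat, flagged=flagged)


def estimate_translation(reference: np.ndarray, moving: np.ndarray,
                         upsample_factor: int = 50) -> np.ndarray:
    """Subpixel 3-D translation registering ``moving`` onto ``reference``."""
    shift, _, _ = phase_cross_correlation(reference, moving,
                                          upsample_factor=upsample_factor,
                                          normalization=None)
    return np.asarray(shift)


def align_repeats(series_list: list[CombinedEchoSeries],
                  reference_echo: int = 1,
                  upsample_factor: int = 50):
    """Translation-only registration of every repeat to the reference
    (second echo of the first repeat).

    Each repeat's translation is estimated on its ``reference_echo``
    magnitude and applied to all of that repeat's magnitude and phase
    volumes (phase translated through its complex exponential, so wrapping
    is respected).  Returns ``(shifts, aligned_series)`` with one 3-vector
    per repeat; a single repeat passes through unchanged with zero shift.
    """
    if not series_list:
        raise ValueError("no repeats supplied")
    ref = series_list[0].magnitude[reference_echo]
    shifts = []
    aligned = []
    for s in series_list:
        if s is series_list[0]:
            shift = np.zeros(3)
            aligned.append(s)
        else:
            shift = estimate_translation(ref, s.magnitude[reference_echo],
                                         upsample_factor=upsample_factor)
            mags = np.stack([translate_fourier(m, shift) for m in s.magnitude])
            phs = np.stack([
                wrap_phase(np.angle(translate_fourier(np.exp(1j * p), shift)))
                for p in s.phase])
            aligned.append(CombinedEchoSeries(
                magnitude=mags, phase=phs,
                effective_echo_times_ms=s.effective_echo_times_ms,
                params=s.params, repeat=s.repeat, flagged=s.flagged))
        shifts.append(shift)
    return np.asarray(shifts), aligned
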