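"""Voxel-wise frequency-offset (field map) estimation from combined echoes.

The frequency offset Δf (Hz) and residual echo-time-independent phase φ0
are estimated per voxel by a nonlinear complex fit across the effective
echoes, assuming linear phase evolution.  The fit is initialized from the
spatially unwrapped first effective echo and the unwrapped phase difference
between the first two effective echoes, which makes the fit robust to
frequency offsets beyond the per-echo-spacing Nyquist limit (|Δf| > π per
ΔTE) where an uninitialized fit can alias by multiples of 1/ΔTE.

φ0 doubles as a goodness-of-fit diagnostic: after offset-free coil
combination it should be near zero wherever phase evolution is truly
linear, so large focal |φ0| flags unreliable voxels (vessels, bubbles)
which are removed from the mask.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .combine import CombinedEchoSeries, wrap_phase


@dataclass
class BrainMask:
    volume: np.ndarray
    provenance: str = "initial"  # initial | phi0-refined | vsharp-eroded

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=bool)
        if not self.volume.any():
            raise ValueError("empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


@dataclass
class FieldMapResult:
    delta_f_Hz: np.ndarray
    phi0_rad: np.ndarray
    rms_residual: np.ndarray
    mask: BrainMask
    repeat: int | str = 0
    converged: np.ndarray | None = None


def generate_mask(first_echo_magnitude: np.ndarray,
                  threshold_frac: float = 0.1) -> BrainMask:
    """Threshold the first-echo magnitude against a fraction of its robust
    (99th-percentile) maximum; keep the largest connected component and
    fill holes."""
    mag = np.asarray(first_echo_magnitude, dtype=float)
    if np.any(mag < 0):
        raise ValueError("magnitude must be non-negative")
    robust_max = np.percentile(mag, 99)
    raw = mag > threshold_frac * robust_max
    if not raw.any():
        raise ValueError(
            f"empty mask: threshold {threshold_frac} x p99 ({robust_max:.3g}) "
            f"exceeds the maximum magnitude {mag.max():.3g}")
    labeled, n = ndimage.label(raw)
    if n > 1:
        counts = np.bincount(labeled.ravel())[1:]
        raw = labeled == (np.argmax(counts) + 1)
    raw = ndimage.binary_fill_holes(raw)
    return BrainMask(volume=raw, provenance="initial")


def _phase_quality(wrapped: np.ndarray) -> np.ndarray:
    """Negative phase-derivative variance in a 3³ neighbourhood (higher is
    better); drives the region-growing order."""
    q = np.zeros(wrapped.shape)
    for ax in range(wrapped.ndim):
        g = wrap_phase(np.diff(wrapped, axis=ax, append=np.take(
            wrapped, [-1], axis=ax)))
        m = ndimage.uniform_filter(g, size=3)
        v = ndimage.uniform_filter(g * g, size=3) - m * m
        q -= v
    return q


def unwrap_phase_3d(wrapped: np.ndarray, mask: BrainMask | np.ndarray) -> np.ndarray:
    """Quality-guided region-growing spatial unwrapping.

    Within each connected mask region the result differs from the input by
    an integer multiple of 2π at every voxel and is spatially continuous
    where the true phase is; the global 2πk of each region is fixed so its
    median lands in [−π, π] (offsets between disconnected regions are
    inherently unconstrained).  Voxels outside the mask pass through
    unchanged.
    """
    m = mask.volume if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    shape = wrapped.shape
    N = wrapped.size
    quality = _phase_quality(wrapped)
    flat_w = wrapped.reshape(-1)
    flat_q = quality.reshape(-1)
    out = flat_w.astype(float).copy()

    # 6-neighbourhood table (−1 where out of bounds)
    idx = np.arange(N).reshape(shape)
    nbrs = np.full((6, N), -1, dtype=np.int64)
    k = 0
    for ax in range(3):
        fwd = np.full(shape, -1, dtype=np.int64)
        bwd = np.full(shape, -1, dtype=np.int64)
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        fwd[tuple(sl_a)] = idx[tuple(sl_b)]
        bwd[tuple(sl_b)] = idx[tuple(sl_a)]
        nbrs[k] = fwd.reshape(-1)
        nbrs[k + 1] = bwd.reshape(-1)
        k += 2

    in_mask = m.reshape(-1)
    visited = np.zeros(N, dtype=bool)
    labeled, ncomp = ndimage.label(m)
    flat_lab = labeled.reshape(-1)
    two_pi = 2 * np.pi

    for comp in range(1, ncomp + 1):
        comp_idx = np.flatnonzero(flat_lab == comp)
        seed = comp_idx[np.argmax(flat_q[comp_idx])]
        visited[seed] = True
        heap = []
        counter = 0

        def push_neighbours(i):
            nonlocal counter
            base = out[i]
            wi = flat_w[i]
            for j in nbrs[:, i]:
                if j >= 0 and in_mask[j] and not visited[j]:
                    d = flat_w[j] - wi
                    d = (d + np.pi) % two_pi - np.pi
                    counter += 1
                    heapq.heappush(heap, (-flat_q[j], counter, j, base + d))

        push_neighbours(seed)
        while heap:
            _, _, j, val = heapq.heappop(heap)
            if visited[j]:
                continue
            visited[j] = True
            out[j] = val
            push_neighbours(j)

        shift = two_pi * np.round(np.median(out[comp_idx]) / two_pi)
        out[comp_idx] -= shift

    return out.reshape(shape)


def initialize_field_fit(series: CombinedEchoSeries,
                         mask: BrainMask) -> tuple[np.ndarray, np.ndarray]:
    """Initial (Δf, φ0) from the first two effective echoes.

    The wrapped difference of the first two effective-echo phases is
    spatially unwrapped and divided by 2πΔTE to give Δf; the unwrapped
    first effective-echo phase minus the predicted linear term gives φ0.
    Only these two images are unwrapped — they carry far fewer wraps than
    the later echoes.
    """
    if series.phase.shape[0] < 2:
        raise ValueError("need at least 2 effective echoes to initialize")
    eff_s = series.effective_echo_times_ms * 1e-3
    p1, p2 = series.phase[0], series.phase[1]
    diff = wrap_phase(np.angle(np.exp(1j * p2) * np.exp(-1j * p1)))
    diff_uw = unwrap_phase_3d(diff, mask)
    delta_f = diff_uw / (2 * np.pi * (eff_s[1] - eff_s[0]))
    p1_uw = unwrap_phase_3d(p1, mask)
    phi0 = p1_uw - 2 * np.pi * delta_f * eff_s[0]
    return delta_f, phi0


def fit_field_nonlinear(series: CombinedEchoSeries, mask: BrainMask,
                        init: tuple[np.ndarray, np.ndarray] | None = None,
                        max_iter: int = 50, tol: float = 1e-10,
                        repeat: int | str | None = None) -> FieldMapResult:
    """Per-voxel nonlinear complex fit of φ0 and Δf across effective echoes.

    Minimizes ‖S_n − |S_n|·e^{i(φ0 + 2πΔf·TE'_n)}‖² with the magnitude
    taken from the data (not fitted).  Solved by damped Gauss–Newton,
    vectorized over all masked voxels; non-convergent voxels keep their
    initialization and are flagged (converged=False) so the φ0-based mask
    refinement can discard them.
    """
    m = mask.volume
    eff_s = series.effective_echo_times_ms * 1e-3  # (n_eff,)
    mags = series.magnitude[1:][:, m]              # (n_eff, nvox)
    S = mags * np.exp(1j * series.phase[:, m])
    if init is None:
        df0, ph0 = initialize_field_fit(series, mask)
    else:
        df0, ph0 = init
    omega = 2 * np.pi * df0[m].astype(float).copy()
    phi0 = ph0[m].astype(float).copy()

    t = eff_s[:, None]
    w2 = mags**2
    # Gauss-Newton normal matrix is parameter-independent for this model
    a11 = w2.sum(axis=0)
    a12 = (w2 * t).sum(axis=0)
    a22 = (w2 * t * t).sum(axis=0)
    det = a11 * a22 - a12 * a12
    det = np.where(det > 0, det, 1.0)

    converged = np.zeros(omega.shape, dtype=bool)
    for _ in range(max_iter):
        model = mags * np.exp(1j * (phi0[None] + omega[None] * t))
        r = S - model
        # Re(conj(∂model/∂p) · r) with ∂model/∂φ0 = i·model
        inner = np.imag(np.conj(model) * r)
        g1 = inner.sum(axis=0)
        g2 = (inner * t).sum(axis=0)
        d_phi = (a22 * g1 - a12 * g2) / det
        d_om = (-a12 * g1 + a11 * g2) / det
        active = ~converged
        phi0[active] += d_phi[active]
        omega[active] += d_om[active]
        newly = (np.abs(d_phi) < tol) & (np.abs(d_om) < tol)
        converged |= newly
        if converged.all():
            break

    model = mags * np.exp(1j * (phi0[None] + omega[None] * t))
    res = np.sqrt(np.mean(np.abs(S - model) ** 2, axis=0))
    # non-convergent voxels fall back to the initialization
    phi0 = np.where(converged, phi0, ph0[m])
    omega = np.where(converged, omega, 2 * np.pi * df0[m])

    delta_f = np.zeros(m.shape)
    phi0_map = np.zeros(m.shape)
    res_map = np.zeros(m.shape)
    conv_map = np.ones(m.shape, dtype=bool)
    delta_f[m] = omega / (2 * np.pi)
    phi0_map[m] = wrap_phase(phi0)
    res_map[m] = res
    conv_map[m] = converged
    return FieldMapResult(delta_f_Hz=delta_f, phi0_rad=phi0_map,
                          rms_residual=res_map, mask=mask,
                          repeat=series.repeat if repeat is None else repeat,
                          converged=conv_map)


def refine_mask_phi0(result: FieldMapResult,
                     phi0_abs_threshold_rad: float = 1.0) -> BrainMask:
    """Drop voxels whose residual |φ0| exceeds the threshold — focal field
    outliers near vessels and bubbles with unreliable phase."""
    if phi0_abs_threshold_rad <= 0:
        raise ValueError("phi0 threshold must be positive")
    m = result.mask.volume
    bad = m & (np.abs(result.phi0_rad) > phi0_abs_threshold_rad)
    refined = m & ~bad
    return BrainMask(volume=refined, provenance="phi0-refined")


def remove_readout_phase_gradient(series: CombinedEchoSeries,
                                  mask: BrainMask) -> CombinedEchoSeries:
    """Remove the eddy-current/readout-mistiming linear phase gradient.

    For each later effective echo n the deviation from linear prediction,
    arg[e^{iΔφ(TE'_n)}·e^{−i·m·Δφ(TE'_1)}] with m = TE'_n/TE'_1, is averaged
    over the non-readout axes inside the mask, a straight line is fitted
    against the readout coordinate, and the fitted line is subtracted from
    that echo's phase.  Requires TE'_n to be integer multiples of TE'_1
    (true for the 6.6·{1..5} ms protocol); otherwise the per-echo ratio is
    used as-is with a warning.
    """
    eff = series.effective_echo_times_ms
    ratios = eff / eff[0]
    if np.any(np.abs(ratios - np.round(ratios)) > 1e-6):
        warnings.warn("effective echo times are not integer multiples of the "
                      "first; using fractional linear prediction")
    params = series.params
    ro = params.readout_axis
    m = mask.volume
    spatial_axes = [0, 1, 2]
    other = tuple(ax for ax in spatial_axes if ax != ro)
    coords = np.arange(series.phase.shape[1 + ro], dtype=float)

    new_phase = series.phase.copy()
    z1 = np.exp(1j * series.phase[0])
    mask_f = m.astype(float)
    denom = mask_f.sum(axis=other)
    valid = denom > 0
    for j in range(1, series.phase.shape[0]):
        mlt = ratios[j]
        dev = np.exp(1j * series.phase[j]) * z1 ** (-mlt)
        prof_c = (dev * mask_f).sum(axis=other)
        prof = np.angle(np.where(valid, prof_c, 1.0))
        x = coords[valid]
        y = prof[valid]
        slope, intercept = np.polyfit(x, y, 1)
        line = slope * coords + intercept
        shp = [1, 1, 1]
        shp[ro] = len(coords)
        new_phase[j] = wrap_phase(series.phase[j] - line.reshape(shp))
    return CombinedEchoSeries(
        magnitude=series.magnitude, phase=new_phase,
        effective_echo_times_ms=series.effective_echo_times_ms,
        params=series.params, repeat=series.repeat, flagged=series.flagged)


@dataclass
class DriftDiagnostics:
    """Per-repeat global mean Δf (Hz) and increments between adjacent
    repeats — the B0-drift signature (mean offsets rise, increments shrink
    as the scanner's passive shim temperature stabilizes)."""

    mean_delta_f_Hz: np.ndarray   # one per repeat
    increments_Hz: np.ndarray     # mean_df[r] − mean_df[r−1]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "repeat": np.arange(1, len(self.mean_delta_f_Hz) + 1),
            "mean_delta_f_Hz": self.mean_delta_f_Hz,
            "increment_Hz": np.concatenate([[np.nan], self.increments_Hz]),
        })


def average_repeat_fields(results: list[FieldMapResult]
                          ) -> tuple[FieldMapResult, DriftDiagnostics]:
    """Average per-repeat Δf maps voxel-wise (masks intersected).

    Averaging the fitted fields rather than the raw phase needs no drift
    correction (a per-repeat global offset averages benignly instead of
    causing phase cancellation) and bounds the influence of a repeat with a
    locally corrupted field by 1/n.  The per-repeat whole-mask mean Δf and
    its increments are returned as the drift diagnostic.
    """
    if not results:
        raise ValueError("no field maps supplied")
    inter = results[0].mask.volume.copy()
    for r in results[1:]:
        inter &= r.mask.volume
    mask = BrainMask(volume=inter, provenance=results[0].mask.provenance)
    stack = np.stack([r.delta_f_Hz for r in results])
    mean_field = stack.mean(axis=0)
    phi0_c = np.mean(np.exp(1j * np.stack([r.phi0_rad for r in results])),
                     axis=0)
    res = np.mean(np.stack([r.rms_residual for r in results]), axis=0)
    means = np.array([r.delta_f_Hz[inter].mean() for r in results])
    diag = DriftDiagnostics(mean_delta_f_Hz=means,
                            increments_Hz=np.diff(means))
    avg = FieldMapResult(delta_f_Hz=np.where(inter, mean_field, 0.0),
                         phi0_rad=wrap_phase(np.angle(phi0_c)),
                         rms_residual=res, mask=mask, repeat="averaged")
    return avg, diag
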