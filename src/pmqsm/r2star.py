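"""R2* relaxometry from multi-echo magnitudes with a noise-floor term.

Magnitude decay is fitted per voxel as M(TE) = M0·exp(−TE·R2*) + noise,
all three parameters non-negative.  The explicit noise-floor term matters
because coil combination leaves Rician-distributed magnitudes whose late
echoes flatten onto the noise floor; omitting the term biases R2* downward.
Final maps are fitted on repeat-averaged magnitudes; per-repeat fits feed
the T2* drift diagnostic (sample-temperature stability check).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AcquisitionParams
from .fieldmap import BrainMask


@dataclass
class R2StarFitResult:
    r2star_per_s: np.ndarray
    m0: np.ndarray
    noise_floor: np.ndarray
    rms_residual: np.ndarray
    mask: BrainMask
    converged: np.ndarray | None = None


@dataclass
class DriftReport:
    """Whole-mask mean T2* per repeat and percent change vs repeat 1.
    No correction is applied when changes stay below the threshold; the
    report only documents temperature stability."""

    mean_t2star_ms: np.ndarray
    percent_change: np.ndarray  # entry 0 is 0 by definition
    correction_threshold_percent: float = 1.0

    @property
    def correction_recommended(self) -> bool:
        return bool(np.any(np.abs(self.percent_change)
                           > self.correction_threshold_percent))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "repeat": np.arange(1, len(self.mean_t2star_ms) + 1),
            "mean_t2star_ms": self.mean_t2star_ms,
            "percent_change_vs_repeat1": self.percent_change,
        })


def _solve3(A, g):
    """Batched 3x3 solve, tolerant of singular voxels (returns zero step)."""
    try:
        return np.linalg.solve(A, g[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.zeros_like(g)
        for i in range(A.shape[0]):
            try:
                out[i] = np.linalg.solve(A[i], g[i])
            except np.linalg.LinAlgError:
                pass
        return out


def fit_r2star(magnitudes: np.ndarray, params: AcquisitionParams,
               mask: BrainMask, fit_noise_floor: bool = True,
               max_iter: int = 200, tol: float = 1e-12) -> R2StarFitResult:
    """Bounded least-squares fit of (M0, R2*, noise) per masked voxel.

    ``magnitudes`` is (n_echoes, x, y, z), normally the repeat-averaged
    series, using all original echo times.  Initialization: noise = min(M),
    M0 = max(M) − noise, R2* from a two-point log-linear estimate on the
    first and third echoes.  Solved with a vectorized projected
    Levenberg–Marquardt; non-convergent voxels keep the log-linear
    initialization and are flagged.  ``fit_noise_floor=False`` pins the
    floor at zero (the 2-parameter comparison model).
    """
    if magnitudes.shape[0] != params.n_echoes:
        raise ValueError("echo count mismatch")
    if np.any(magnitudes < 0):
        raise ValueError("magnitudes must be non-negative")
    m = mask.volume
    te = np.asarray(params.echo_times_ms) * 1e-3  # seconds
    M = magnitudes[:, m].astype(float)            # (n_echo, nvox)
    nvox = M.shape[1]

    c = M.min(axis=0) if fit_noise_floor else np.zeros(nvox)
    m0 = np.maximum(M.max(axis=0) - c, 1e-12)
    d1 = np.maximum(M[0] - c, 1e-12)
    d3 = np.maximum(M[2] - c, 1e-12)
    r2 = np.maximum(np.log(d1 / d3) / (te[2] - te[0]), 0.0)
    init = np.stack([m0, r2, c], axis=1)

    p = init.copy()
    lam = np.full(nvox, 1e-3)
    t = te[:, None]

    def cost(pv):
        model = pv[:, 0] * np.exp(-t * pv[:, 1]) + pv[:, 2]
        return ((M - model) ** 2).sum(axis=0)

    cur = cost(p)
    converged = np.zeros(nvox, dtype=bool)
    for _ in range(max_iter):
        E = np.exp(-t * p[:, 1])                    # (n_echo, nvox)
        model = p[:, 0] * E + p[:, 2]
        r = M - model
        J0 = E
        J1 = -p[:, 0] * t * E
        J2 = np.ones_like(E)
        Js = (J0, J1, J2)
        A = np.empty((nvox, 3, 3))
        g = np.empty((nvox, 3))
        for i in range(3):
            g[:, i] = (Js[i] * r).sum(axis=0)
            for j in range(i, 3):
                A[:, i, j] = A[:, j, i] = (Js[i] * Js[j]).sum(axis=0)
        if not fit_noise_floor:  # pin the floor at zero
            A[:, 2, :] = A[:, :, 2] = 0.0
            A[:, 2, 2] = 1.0
            g[:, 2] = 0.0
        diag = np.maximum(A[:, (0, 1, 2), (0, 1, 2)], 1e-12)
        Ad = A.copy()
        Ad[:, (0, 1, 2), (0, 1, 2)] += lam[:, None] * diag
        step = _solve3(Ad, g)
        p_new = np.maximum(p + step, 0.0)
        new = cost(p_new)
        better = new <= cur
        act = better & ~converged
        rel_step = np.abs(p_new - p).max(axis=1) / (1.0 + np.abs(p).max(axis=1))
        converged |= better & (rel_step < tol)
        p[act] = p_new[act]
        cur[act] = new[act]
        lam = np.where(better, lam * 0.3, lam * 10.0)
        lam = np.clip(lam, 1e-12, 1e12)
        if converged.all():
            break

    # fall back to initialization where the solver never improved the cost
    fell_back = cur > cost(init) + 1e-30
    p[fell_back] = init[fell_back]
    model = p[:, 0] * np.exp(-t * p[:, 1]) + p[:, 2]
    rms = np.sqrt(np.mean((M - model) ** 2, axis=0))

    shape = m.shape
    out = R2StarFitResult(
        r2star_per_s=np.zeros(shape), m0=np.zeros(shape),
        noise_floor=np.zeros(shape), rms_residual=np.zeros(shape),
        mask=mask, converged=np.ones(shape, dtype=bool))
    out.m0[m] = p[:, 0]
    out.r2star_per_s[m] = p[:, 1]
    out.noise_floor[m] = p[:, 2]
    out.rms_residual[m] = rms
    out.converged[m] = converged & ~fell_back
    return out


def assess_t2star_drift(per_repeat_magnitudes: np.ndarray,
                        params: AcquisitionParams, mask: BrainMask,
                        r2s_floor_per_s: float = 1.0,
                        correction_threshold_percent: float = 1.0
                        ) -> DriftReport:
    """Per-repeat whole-mask mean T2* and its percent change vs repeat 1.

    T2* (ms) is averaged over voxels with R2* above ``r2s_floor_per_s``
    (avoids 1/0 in near-flat voxels).  The pipeline applies no correction;
    the report flags whether one would be warranted.
    """
    n_rep = per_repeat_magnitudes.shape[0]
    if n_rep < 2:
        raise ValueError("need at least two repeats to assess drift")
    means = []
    valid_common = None
    fits = []
    for rmag in per_repeat_magnitudes:
        if not np.any(rmag):
            raise ValueError("repeat with all-zero magnitudes")
        fit = fit_r2star(rmag, params, mask)
        fits.append(fit)
        v = mask.volume & (fit.r2star_per_s > r2s_floor_per_s)
        valid_common = v if valid_common is None else (valid_common & v)
    for fit in fits:
        t2 = 1000.0 / fit.r2star_per_s[valid_common]
        means.append(t2.mean())
    means = np.asarray(means)
    pct = 100.0 * (means - means[0]) / means[0]
    return DriftReport(mean_t2star_ms=means, percent_change=pct,
                       correction_threshold_percent=correction_threshold_percent)
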