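"""ROI summarization and the group/histology statistics layer.

ROI means of χ and R2* use scaled-MAD outlier rejection (robust to bubble
and vessel voxels inside anatomical masks).  Stained-area fractions (SAF)
from immunohistochemistry arrive as tabular input and are standardized
within staining batch to absorb technician/batch intensity bias — after
which ferritin "fractions" can legitimately be negative.  Group contrasts
use Welch's t with Hedges's g effect sizes; susceptibility–histology
associations use Pearson and first-order partial correlations.  p-values
are two-tailed with α = 0.05 and no multiple-comparison correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Normal-consistency constant making the MAD estimate the SD of a Gaussian.
MAD_SCALE = 1.4826


@dataclass
class ROIDefinition:
    label: str
    mask: np.ndarray
    hemisphere: str = "both"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI '{self.label}' has an empty mask")


def mad_outlier_filter(values, k: float = 3.0):
    """Exclude values more than k scaled-MADs from the median.

    scaledMAD = 1.4826 · median(|x − median(x)|).  The comparison is a
    strict inequality, so with all values equal nothing is excluded, while
    a zero MAD with a deviant minority excludes exactly the deviants.
    Returns ``(kept_values, outlier_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    out_idx = np.flatnonzero(np.abs(x - med) > k * smad)
    keep = np.delete(x, out_idx)
    return keep, out_idx


def roi_summary(map_volume: np.ndarray, roi: ROIDefinition, k: float = 3.0,
                alarm_fraction: float = 0.5) -> dict:
    """Mean of a map over an ROI after scaled-MAD outlier rejection."""
    vals = np.asarray(map_volume)[roi.mask]
    kept, out_idx = mad_outlier_filter(vals, k=k)
    if kept.size == 0:
        raise ValueError(
            f"ROI '{roi.label}': all {vals.size} voxels rejected as outliers")
    frac = out_idx.size / vals.size
    if frac > alarm_fraction:
        import warnings
        warnings.warn(f"ROI '{roi.label}': {100 * frac:.1f}% of voxels "
                      "rejected as outliers")
    return {"roi": roi.label, "hemisphere": roi.hemisphere,
            "mean": float(kept.mean()), "n_voxels": int(vals.size),
            "n_outliers_removed": int(out_idx.size)}


def standardize_saf(records: pd.DataFrame, by: str = "batch",
                    value_col: str = "saf", ddof: int = 1) -> pd.DataFrame:
    """Within-batch z-standardization of stained-area fractions.

    Demeans and divides by the (sample, ddof=1 by default) SD within each
    batch; adds a ``saf_std`` column.  Single-record batches and zero
    within-batch variance are rejected.
    """
    df = records.copy()
    if (df[value_col] < 0).any() or (df[value_col] > 1).any():
        raise ValueError("raw SAF values must lie in [0, 1]")
    out = np.empty(len(df))
    for _, idx in df.groupby(by).groups.items():
        v = df.loc[idx, value_col].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError("batch with fewer than 2 records")
        sd = v.std(ddof=ddof)
        if sd == 0:
            raise ValueError("zero within-batch variance")
        out[df.index.get_indexer(idx)] = (v - v.mean()) / sd
    df["saf_std"] = out
    return df


def _residualize(y, x):
    """OLS residuals of y on [1, x]."""
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def correlation_suite(x, y, covariate=None) -> dict:
    """Pearson correlation, plus a first-order partial correlation when a
    covariate is given (the covariate is regressed out of both variables
    and the residuals correlated — identical to the closed-form
    (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    out = {"r": float(r), "p": float(p), "n": int(x.size)}
    if covariate is not None:
        z = np.asarray(covariate, dtype=float)
        if z.size != x.size or x.size < 4:
            raise ValueError("partial correlation needs n >= 4")
        if np.std(z) == 0:
            raise ValueError("zero variance covariate")
        rx = _residualize(x, z)
        ry = _residualize(y, z)
        rp, _ = sps.pearsonr(rx, ry)
        # p-value with one df spent on the covariate
        n = x.size
        dfree = n - 3
        tstat = rp * np.sqrt(dfree / max(1e-300, 1 - rp**2))
        pp = 2 * sps.t.sf(abs(tstat), dfree)
        out.update({"partial_r": float(rp), "partial_p": float(pp)})
    return out


def hedges_g(a, b) -> float:
    """Small-sample-corrected standardized mean difference.

    Cohen's d with pooled SD, shrunk by J = 1 − 3/(4ν − 1), ν = n_a+n_b−2.
    Positive when mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    nu = na + nb - 2
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / nu)
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    d = (a.mean() - b.mean()) / sp
    J = 1.0 - 3.0 / (4.0 * nu - 1.0)
    return float(J * d)


def group_comparison(group_a, group_b) -> dict:
    """Welch's t-test (Satterthwaite df) with Hedges's g effect size."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": np.nan, "df": np.nan, "p": 1.0, "g": 0.0,
                    "note": "t undefined: zero variance, equal means"}
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return {"t": float(res.statistic), "df": float(df),
            "p": float(res.pvalue), "g": hedges_g(a, b)}


def regress_out_covariate(values, covariate) -> np.ndarray:
    """OLS-residualize values against a covariate, restoring the grand mean
    so units are preserved.  The covariate may be a binary indicator (e.g.
    fixative type) or continuous."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant covariate")
    return _residualize(y, x) + y.mean()
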