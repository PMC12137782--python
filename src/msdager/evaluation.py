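"""Quantitative evaluation of reconstructions.

nRMSE against ground truth, the angular-covariance profile (does the GP
prior smooth across directions?), the cross-shell intensity ratio (does it
smooth across shells?) and the weighted-DICE overlap of tract-density maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import ImageSeries
from .gp import angular_distance
from .scheme import QSpaceScheme


def nrmse(recon: ImageSeries | np.ndarray, truth: ImageSeries | np.ndarray,
          mask: np.ndarray | None = None) -> float:
    """|| |recon| - |truth| ||_2 / || |truth| ||_2 over masked voxels, all volumes."""
    r = recon.data if isinstance(recon, ImageSeries) else np.asarray(recon)
    t = truth.data if isinstance(truth, ImageSeries) else np.asarray(truth)
    if r.shape != t.shape:
        raise ValueError("shape mismatch between reconstruction and truth")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if not np.any(m):
            raise ValueError("empty mask")
        r = r[:, m] if r.ndim > m.ndim else r[m]
        t = t[:, m] if t.ndim > m.ndim else t[m]
    denom = np.linalg.norm(np.abs(t))
    if denom == 0:
        raise ValueError("zero-norm reference")
    return float(np.linalg.norm(np.abs(r) - np.abs(t)) / denom)


def angular_covariance_profile(series: ImageSeries, mask: np.ndarray,
                               bin_width_deg: float = 5.0):
    """Same-shell signal covariance versus angular distance.

    For every same-shell direction pair, the covariance of masked voxel
    signals; binned by antipodal angular distance and normalized by the
    median same-direction variance (so the 0-degree bin is 1 by
    construction).  Empty bins are NaN.  Returns (bin centers in degrees,
    normalized covariance per bin).
    """
    scheme = series.scheme
    dwi = scheme.dwi_indices
    if dwi.size < 2:
        raise ValueError("need at least two DWI volumes")
    mag = series.magnitude()[dwi][:, np.asarray(mask, dtype=bool)]  # (Nd, V)
    sub = scheme.subset(dwi)
    centered = mag - mag.mean(axis=1, keepdims=True)
    nv = mag.shape[1]
    cov = centered @ centered.T / (nv - 1)
    norm = np.median(np.diag(cov))

    g = sub.bvecs
    theta = np.rad2deg(np.arccos(np.clip(np.abs(g @ g.T), -1, 1)))
    same_shell = sub.shell_ids[:, None] == sub.shell_ids[None, :]
    iu = np.triu_indices(len(g))  # include the diagonal: the 0-degree bin
    pair_theta = theta[iu][same_shell[iu]]
    pair_cov = cov[iu][same_shell[iu]]

    n_bins = int(np.ceil(90.0 / bin_width_deg))
    centers = (np.arange(n_bins) + 0.5) * bin_width_deg
    prof = np.full(n_bins, np.nan)
    idx = np.minimum((pair_theta / bin_width_deg).astype(int), n_bins - 1)
    for k in range(n_bins):
        sel = idx == k
        if np.any(sel):
            prof[k] = np.mean(pair_cov[sel]) / norm
    return centers, prof


def cross_shell_ratio(series: ImageSeries, mask: np.ndarray,
                      shells: tuple | None = None):
    """Voxel-wise ratio of direction-averaged images, lower b over higher b.

    Returns a dict with the per-voxel ratios over the mask, their median and
    mean, a histogram, and the number of zero-denominator voxels excluded.
    """
    scheme = series.scheme
    shell_b = sorted(set(float(scheme.shells[i]) for i in
                         np.unique(scheme.shell_ids[scheme.dwi_indices])))
    if shells is None:
        if len(shell_b) != 2:
            raise ValueError("select exactly two shells for the ratio")
        lo_b, hi_b = shell_b
    else:
        lo_b, hi_b = sorted(shells)
    mag = series.magnitude()
    m = np.asarray(mask, dtype=bool)

    def shell_mean(b):
        sel = np.abs(scheme.bvals - b) <= 50.0
        return mag[sel].mean(axis=0)

    num = shell_mean(lo_b)[m]
    den = shell_mean(hi_b)[m]
    ok = den > 0
    ratio = num[ok] / den[ok]
    hist, edges = np.histogram(ratio, bins=50)
    return {"ratio": ratio, "median": float(np.median(ratio)),
            "mean": float(np.mean(ratio)), "hist": hist, "bin_edges": edges,
            "n_excluded": int(np.sum(~ok)), "shells": (lo_b, hi_b)}


def ratio_decrease_percent(recon: ImageSeries, truth: ImageSeries,
                           mask: np.ndarray, statistic: str = "median") -> float:
    """Relative decrease (%) of the cross-shell intensity ratio vs truth.

    Positive means the reconstruction's low-b/high-b ratio is lower than the
    ground truth's, the signature of cross-shell smoothing.
    """
    rr = cross_shell_ratio(recon, mask)
    rt = cross_shell_ratio(truth, mask)
    a, b = rr[statistic], rt[statistic]
    return float(100.0 * (b - a) / b)


@dataclass
class TractDensity:
    """Per-voxel fraction in [0, 1] of streamlines passing through."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("tract-density weights must lie in [0, 1]")
        self.weights = w


def weighted_dice(wi: TractDensity | np.ndarray, wj: TractDensity | np.ndarray,
                  threshold: float = 0.0) -> float:
    """Weighted overlap of two tract-density maps.

    (sum over the support intersection of wi + wj) / (total sum of wi + wj),
    where the intersection is the set of voxels with both weights above
    ``threshold`` (default 0: strictly positive).  Symmetric, in [0, 1].
    """
    a = wi.weights if isinstance(wi, TractDensity) else TractDensity(np.asarray(wi)).weights
    b = wj.weights if isinstance(wj, TractDensity) else TractDensity(np.asarray(wj)).weights
    if a.shape != b.shape:
        raise ValueError("tract maps must share a grid")
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("both tract maps are empty")
    inter = (a > threshold) & (b > threshold)
    return float((a[inter].sum() + b[inter].sum()) / total)
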