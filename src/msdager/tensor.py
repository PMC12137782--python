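"""Linear least-squares diffusion-tensor fit for FA/MD tissue masks.

Not a DTI analysis feature: the reconstruction needs white/gray tissue masks
to fit GP hyperparameters per tissue class, and those masks come from FA/MD
thresholds (FA > 0.2 and MD > 0.0003 mm^2/s for white matter; FA < 0.2 and
MD < 0.0009 mm^2/s for gray matter) applied to a quick log-linear tensor fit
of the current reconstruction.
"""

from __future__ import annotations

import numpy as np

from .scheme import QSpaceScheme

FA_THRESHOLD = 0.2
MD_WHITE_MIN = 0.0003  # mm^2/s
MD_GRAY_MAX = 0.0009  # mm^2/s


def design_matrix(scheme: QSpaceScheme) -> np.ndarray:
    """log-signal DTI design: columns [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def fit_fa_md(signals: np.ndarray, scheme: QSpaceScheme,
              min_signal: float = 1e-6):
    """Per-voxel FA and MD from magnitude signals (V, Nd)."""
    y = np.log(np.maximum(np.atleast_2d(signals), min_signal))
    X = design_matrix(scheme)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    D = np.empty(y.shape[:1] + (3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = dxx, dyy, dzz
    D[:, 0, 1] = D[:, 1, 0] = dxy
    D[:, 0, 2] = D[:, 2, 0] = dxz
    D[:, 1, 2] = D[:, 2, 1] = dyz
    evals = np.linalg.eigvalsh(D)
    md = evals.mean(axis=1)
    dev = evals - md[:, None]
    denom = np.sum(evals ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * np.sum(dev ** 2, axis=1) / np.maximum(denom, 1e-30))
    fa = np.clip(np.nan_to_num(fa), 0, 1)
    return fa, md


def tissue_labels(signals: np.ndarray, scheme: QSpaceScheme,
                  support: np.ndarray) -> np.ndarray:
    """String labels per voxel-row: white / gray / other / background."""
    fa, md = fit_fa_md(signals, scheme)
    labels = np.full(fa.shape, "background", dtype=object)
    sup = np.asarray(support, dtype=bool).ravel()
    white = sup & (fa > FA_THRESHOLD) & (md > MD_WHITE_MIN)
    gray = sup & (fa < FA_THRESHOLD) & (md < MD_GRAY_MAX)
    labels[sup] = "other"
    labels[gray] = "gray"
    labels[white] = "white"
    return labels.astype(str)
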