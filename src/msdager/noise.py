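"""Rician-aware noise estimation and g-factor correction.

Magnitude MRI data carry Rician noise: the sample standard deviation of the
magnitude underestimates the underlying complex-channel noise SD sigma, badly
so at low SNR (by 35% in pure-noise regions).  A naive Gaussian estimate
therefore shows a strong negative bias that grows with the noise level.

The variance-stabilizing estimate here works in two stages:

1. a robust magnitude-domain noise SD from spatial pseudo-residuals
   (each voxel minus the mean of its 4 in-plane neighbors, scaled by
   sqrt(4/5) so the residual variance equals the noise variance), summarized
   by the median absolute deviation across volumes;
2. an analytic Rician correction-factor fixed point: the local mean/SD ratio
   determines the underlying SNR theta = A/sigma through the identities
   E[z] = sigma sqrt(pi/2) L(-theta^2/2) and Var[z] = xi(theta) sigma^2 with
   xi(theta) = 2 + theta^2 - (pi/2) L^2(-theta^2/2), where L is the Laguerre
   polynomial of order 1/2.  Iterating theta <- sqrt(xi(theta)(1 + r^2) - 2)
   converges to the value whose corrected variance sigma^2 = s^2/xi(theta)
   is independent of the local signal level, which is precisely the
   variance-stabilization criterion; an 8-bin flatness diagnostic of the
   corrected SD versus intensity is reported.

Parallel-imaging reconstructions amplify noise spatially by the g-factor;
sigma maps are divided by the analytic SENSE g-factor (aliasing-matrix
formulation on the CAIPI-collapsed 3D problem) before spatial averaging.

With the unitary FFT convention used throughout, white noise has identical
variance in k-space and image space, so sigma_k^2 = sigma_n^2 per shell up
to coil combination with unit sum-of-squares maps; the conversion is the
identity and round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from .sampling import SamplingPattern

#: mean/SD ratio of a Rayleigh variable, the theta=0 fixed-point boundary
_RAYLEIGH_RATIO = np.sqrt(np.pi / (4 - np.pi))


def _laguerre_half(theta2: np.ndarray) -> np.ndarray:
    """L_{1/2}(-theta^2/2), computed with scaled Bessel functions."""
    t = theta2 / 4.0
    return (1 + theta2 / 2) * i0e(t) + (theta2 / 2) * i1e(t)


def rician_xi(theta) -> np.ndarray:
    """Variance correction factor: Var[z] = xi(theta) * sigma^2."""
    theta2 = np.asarray(theta, dtype=float) ** 2
    return 2 + theta2 - (np.pi / 2) * _laguerre_half(theta2) ** 2


def koay_theta(ratio, iters: int = 25) -> np.ndarray:
    """Invert the Rician mean/SD ratio to the underlying SNR theta = A/sigma.

    Fixed point theta <- sqrt(xi(theta)(1 + ratio^2) - 2); ratios at or below
    the Rayleigh bound map to theta = 0.
    """
    r = np.asarray(ratio, dtype=float)
    theta = np.maximum(r - _RAYLEIGH_RATIO, 0.0)
    low = r <= _RAYLEIGH_RATIO
    for _ in range(iters):
        arg = rician_xi(theta) * (1 + r ** 2) - 2
        theta = np.sqrt(np.maximum(arg, 0.0))
    theta[low] = 0.0
    return theta


def pseudo_residuals(img: np.ndarray) -> np.ndarray:
    """In-plane 4-neighbor pseudo-residuals over the last two axes.

    r = sqrt(4/5) * (z - mean of 4 neighbors); for i.i.d. noise on a locally
    smooth signal, Var[r] equals the noise variance.
    """
    up = np.roll(img, 1, axis=-2)
    down = np.roll(img, -1, axis=-2)
    left = np.roll(img, 1, axis=-1)
    right = np.roll(img, -1, axis=-1)
    return np.sqrt(4.0 / 5.0) * (img - 0.25 * (up + down + left + right))


def naive_sigma_estimate(magnitude: np.ndarray) -> np.ndarray:
    """Gaussian-assumption noise SD map: MAD of pseudo-residuals pooled over
    volumes and a 3x3 in-plane window, no Rician correction.  Negatively
    biased at low SNR (the "w/o VST" behavior)."""
    from scipy import ndimage
    mag = _as_stack(magnitude)
    r = np.abs(pseudo_residuals(mag))
    med_v = np.median(r, axis=0)
    return 1.4826 * ndimage.median_filter(med_v, size=3)


def vst_estimate_sigma(magnitude: np.ndarray, return_theta: bool = False):
    """Per-voxel estimate of the complex-channel noise SD from magnitude data.

    ``magnitude`` is a stack (volumes or slices along axis 0, in-plane last
    two axes); the estimate is reduced over axis 0.  Unbiased to within ~10%
    for Rician data across SNR 1.875-30 (the noise levels of interest here);
    at SNR ~1 the mean/SD inversion sits on its steepest flank and the bias
    grows to ~13%.
    """
    from scipy import ndimage
    mag = _as_stack(magnitude)
    if not np.any(mag > 0):
        raise ValueError("all-zero magnitude input")
    s_mag = naive_sigma_estimate(mag)
    # spatially pooled local mean stabilizes the steep low-SNR inversion
    local_mean = ndimage.uniform_filter(np.mean(mag, axis=0), size=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_mag > 0, local_mean / np.maximum(s_mag, 1e-30), np.inf)
    theta = koay_theta(np.minimum(ratio, 1e6))
    sigma = np.where(s_mag > 0, s_mag / np.sqrt(rician_xi(theta)), 0.0)
    if return_theta:
        return sigma, theta
    return sigma


def _as_stack(magnitude: np.ndarray) -> np.ndarray:
    mag = np.asarray(magnitude, dtype=float)
    if np.any(mag < 0):
        raise ValueError("magnitudes must be nonnegative")
    if mag.ndim == 2:
        mag = mag[None]
    elif mag.ndim > 4:
        mag = mag.reshape(-1, *mag.shape[-3:])
    return mag


def stabilized_flatness(magnitude: np.ndarray, n_bins: int = 8) -> dict:
    """Corrected noise SD per intensity bin — the stabilization diagnostic.

    After a successful variance-stabilizing correction the per-bin SDs are
    flat (signal-independent); returns the bin SDs and the maximum relative
    deviation from their median.
    """
    mag = _as_stack(magnitude)
    sigma_map = vst_estimate_sigma(mag)
    intensity = np.mean(mag, axis=0)
    ok = sigma_map > 0
    edges = np.quantile(intensity[ok], np.linspace(0, 1, n_bins + 1))
    bin_sigma = []
    for k in range(n_bins):
        m = ok & (intensity >= edges[k]) & (intensity <= edges[k + 1])
        bin_sigma.append(float(np.median(sigma_map[m])) if m.sum() >= 10 else np.nan)
    bin_sigma = np.array(bin_sigma)
    ref = np.nanmedian(bin_sigma)
    dev = float(np.nanmax(np.abs(bin_sigma - ref)) / ref) if ref > 0 else np.nan
    return {"bin_sigma": bin_sigma, "max_rel_deviation": dev}


# ---------------------------------------------------------------------------
# g-factor

def _alias_offsets(pattern: SamplingPattern, n_ky: int, n_kz: int) -> np.ndarray:
    """(dz, dy) aliasing offsets of a CAIPI pattern, from its point-spread
    function (partial Fourier ignored: offsets come from the full lattice)."""
    full = SamplingPattern(pattern.R_inplane, pattern.SMS, pattern.ky_shift,
                           pattern.kz_shift, 1.0, pattern.delta_kz, pattern.blip)
    m = full.mask(n_ky, n_kz).astype(float)
    psf = np.fft.ifft2(m)
    peaks = np.abs(psf) / np.abs(psf).max() > 1e-6
    offs = np.argwhere(peaks)
    expected = pattern.R_inplane * pattern.SMS
    if len(offs) != expected:
        raise ValueError(
            f"pattern is not a clean lattice on this grid ({len(offs)} PSF peaks, "
            f"expected {expected}); use grid sizes divisible by R and SMS")
    return offs  # rows of (dz, dy)


def gfactor_map(sens: np.ndarray, pattern: SamplingPattern,
                support: np.ndarray | None = None) -> np.ndarray:
    """Analytic SENSE g-factor for the combined in-plane x slice pattern.

    g_v = sqrt([(C^H C)^+]_vv [C^H C]_vv) with C the coil-sensitivity
    columns of all voxels aliased onto v.  The pseudo-inverse covers the
    rank-deficient case (total acceleration beyond the coil count), where it
    describes the noise amplification of the minimum-norm least-squares
    (CG-SENSE) reconstruction; voxels with no sensitivity at all get +inf.
    """
    nc, nz, ny, nx = sens.shape
    offs = _alias_offsets(pattern, ny, nz)
    g = np.ones((nz, ny, nx))
    for z in range(nz):
        for y in range(ny):
            zz = (z + offs[:, 0]) % nz
            yy = (y + offs[:, 1]) % ny
            cols = sens[:, zz, yy, :]  # (nc, L, nx)
            gram = np.einsum("clx,cmx->xlm", np.conj(cols), cols)
            self_idx = int(np.flatnonzero((offs[:, 0] == 0) & (offs[:, 1] == 0))[0])
            for x in range(nx):
                if support is not None and not support[z, y, x]:
                    continue
                G = gram[x]
                if G[self_idx, self_idx].real < 1e-12:
                    g[z, y, x] = np.inf
                    continue
                inv = np.linalg.pinv(G, rcond=1e-10, hermitian=True)
                val = (inv[self_idx, self_idx] * G[self_idx, self_idx]).real
                g[z, y, x] = np.sqrt(max(val, 1.0 - 1e-9))
    return g


def effective_gfactor(sens: np.ndarray, masks: np.ndarray, solver,
                      seed: int = 0, n_patterns: int = 2) -> float:
    """Noise amplification of the actual (truncated-CG) SENSE initialization.

    The analytic g-factor describes the exact least-squares reconstruction;
    when the total acceleration exceeds the coil count that solution is
    rank-deficient and the practical CG solver is implicitly regularized by
    early stopping, amplifying noise far less than the analytic value.  This
    propagates one seeded unit-variance complex noise realization through
    ``solver`` (a callable mask, kspace -> image) for a few representative
    patterns and returns the RMS image noise per unit k-space noise.
    """
    rng = np.random.default_rng(seed)
    nc = sens.shape[0]
    uniq = np.unique(masks.reshape(len(masks), -1), axis=0)[:n_patterns]
    amps = []
    for flat in uniq:
        m = flat.reshape(masks.shape[1:]).astype(bool)
        shape = (nc,) + sens.shape[1:]
        d = (rng.normal(size=shape) + 1j * rng.normal(size=shape))
        d *= m[None, :, :, None]
        img = solver(m, d)
        # unit per-channel k-noise -> complex variance 2; report per-channel
        amps.append(np.sqrt(np.mean(np.abs(img) ** 2) / 2.0))
    return float(np.mean(amps))


def corrected_sigma(sigma_map: np.ndarray, g_map: np.ndarray,
                    support: np.ndarray):
    """g-factor-corrected spatial average: mean over the support of
    (sigma/g)^2.  Returns (SD, variance)."""
    if sigma_map.shape != g_map.shape:
        raise ValueError("sigma and g-factor maps must share a grid")
    m = np.asarray(support, dtype=bool)
    if not np.any(m):
        raise ValueError("empty support mask")
    ok = m & np.isfinite(g_map) & (g_map > 0)
    var = float(np.mean((sigma_map[ok] / g_map[ok]) ** 2))
    return float(np.sqrt(var)), var


def sigma_k2_from_sigma_n2(sigma_n2):
    """k-space noise variance from image-space noise variance.

    Identity under the package's unitary FFT and unit-SoS coil combination;
    kept as an explicit, documented conversion point.
    """
    return np.asarray(sigma_n2, dtype=float) * 1.0


@dataclass
class NoiseEstimate:
    """Bundle of noise statistics feeding the GP fit and the data term."""

    sigma_map: np.ndarray
    sigma_scalar: float
    gfactor: np.ndarray
    sigma_k2: float
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"sigma_scalar": float(self.sigma_scalar),
                "sigma_k2": float(self.sigma_k2),
                "gfactor_median": float(np.median(self.gfactor[np.isfinite(self.gfactor)])),
                **{k: v for k, v in self.diagnostics.items()
                   if np.isscalar(v)}}
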