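"""SENSE + simultaneous-multislice encoding operators and baseline reconstruction.

The forward model per diffusion direction is d = Omega F S P u: a smooth
per-direction phase error P (shot-to-shot motion phase), coil sensitivity
weighting S, a unitary DC-centered FFT F over (kz, ky, kx) — the SMS slice
group is encoded as a kz partition axis — and the CAIPI sampling mask Omega.

Arrays: images are complex (nz, ny, nx); k-space is (ncoil, nz, ny, nx);
masks are (nz, ny) booleans broadcast along the fully sampled kx axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import SamplingAssignment
from .scheme import QSpaceScheme


def fft3(x: np.ndarray) -> np.ndarray:
    """Unitary, DC-centered 3D FFT over the last three axes."""
    axes = (-3, -2, -1)
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x, axes=axes),
                                       axes=axes, norm="ortho"), axes=axes)


def ifft3(x: np.ndarray) -> np.ndarray:
    axes = (-3, -2, -1)
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x, axes=axes),
                                        axes=axes, norm="ortho"), axes=axes)


@dataclass
class ImageSeries:
    """Complex image stack across diffusion directions on a common grid."""

    data: np.ndarray  # (Nd, nz, ny, nx) complex
    scheme: QSpaceScheme

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ImageSeries data must be (Nd, nz, ny, nx)")
        if self.data.shape[0] != self.scheme.n_volumes:
            raise ValueError("direction count does not match scheme")

    @property
    def grid_shape(self):
        return self.data.shape[1:]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_directions(self) -> int:
        return self.data.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class KSpaceDataset:
    """Per-direction multi-coil undersampled k-space with its metadata."""

    data: np.ndarray  # (Nd, ncoil, nz, ny, nx) complex
    masks: np.ndarray  # (Nd, nz, ny) bool
    sens: np.ndarray  # (ncoil, nz, ny, nx) complex
    scheme: QSpaceScheme
    assignment: SamplingAssignment | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        nd, nc, nz, ny, nx = self.data.shape
        if self.masks.shape != (nd, nz, ny):
            raise ValueError(f"mask shape {self.masks.shape} != {(nd, nz, ny)}")
        if self.sens.shape != (nc, nz, ny, nx):
            raise ValueError(f"sens shape {self.sens.shape} inconsistent with data")
        if nd != self.scheme.n_volumes:
            raise ValueError("direction count does not match scheme")

    @property
    def grid_shape(self):
        return self.data.shape[2:]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]


def forward(u: np.ndarray, sens: np.ndarray, mask: np.ndarray,
            phase: np.ndarray | None = None) -> np.ndarray:
    """Omega F S P u for one direction.

    ``u`` (nz, ny, nx); ``phase`` in radians (P = exp(i*phase)); returns
    (ncoil, nz, ny, nx) with unsampled entries exactly zero.
    """
    if u.shape != sens.shape[1:]:
        raise ValueError("image/sensitivity grid mismatch")
    x = u * np.exp(1j * phase) if phase is not None else u
    k = fft3(sens * x[None])
    return k * mask[None, :, :, None]


def adjoint(d: np.ndarray, sens: np.ndarray, mask: np.ndarray,
            phase: np.ndarray | None = None) -> np.ndarray:
    """(Omega F S P)^H d; exact adjoint of :func:`forward`."""
    if d.shape != sens.shape:
        raise ValueError("data/sensitivity shape mismatch")
    x = ifft3(d * mask[None, :, :, None])
    u = np.sum(np.conj(sens) * x, axis=0)
    if phase is not None:
        u = u * np.exp(-1j * phase)
    return u


def _cg(apply_A, b: np.ndarray, tol: float, max_iter: int):
    """Conjugate gradients on a Hermitian PSD normal system, any array shape.

    Returns (x, relative-residual history).  The residual norm is not
    monotone for ill-conditioned systems (only the A-norm error is), so the
    loop runs to tolerance or ``max_iter`` and returns the lowest-residual
    iterate seen; it bails out early only on a catastrophic (100x) residual
    blow-up, which signals numerical breakdown rather than normal CG
    oscillation.
    """
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    b_norm = np.sqrt(float(np.vdot(b, b).real))
    if b_norm == 0:
        return x, [0.0]
    hist = [np.sqrt(rs) / b_norm]
    best_x, best_r = x, hist[0]
    for _ in range(max_iter):
        Ap = apply_A(p)
        pAp = float(np.vdot(p, Ap).real)
        if pAp <= 0:
            break  # loss of positive-definiteness: stop at best iterate
        alpha = rs / pAp
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = float(np.vdot(r, r).real)
        rel = np.sqrt(rs_new) / b_norm
        hist.append(rel)
        if rel < best_r:
            best_x, best_r = x, rel
        elif rel > 100 * best_r:
            break
        if rel < tol:
            return x, hist
        p = r + (rs_new / rs) * p
        rs = rs_new
    return best_x, hist


def sense_reconstruct(dataset: KSpaceDataset, phase: np.ndarray | None = None,
                      tol: float = 1e-6, max_iter: int = 15) -> ImageSeries:
    """Per-direction least-squares CG-SENSE: min ||Omega F S P u - d||^2.

    For underdetermined patterns CG on the normal equations converges to the
    minimum-norm solution (zero initialization keeps iterates in the row
    space).  When the total acceleration exceeds the coil count the exact
    minimum-norm solution amplifies noise enormously; the truncated iteration
    count acts as the customary implicit regularization, so ``max_iter`` is
    an image-quality parameter, not merely a convergence bound.
    """
    nd = dataset.scheme.n_volumes
    out = np.empty((nd,) + dataset.grid_shape, dtype=complex)
    for j in range(nd):
        ph = phase[j] if phase is not None else None
        m, s = dataset.masks[j], dataset.sens

        def normal_op(x, m=m, s=s, ph=ph):
            return adjoint(forward(x, s, m, ph), s, m, ph)

        b = adjoint(dataset.data[j], s, m, ph)
        out[j], _ = _cg(normal_op, b, tol, max_iter)
    return ImageSeries(out, dataset.scheme)


def _hann_window(n: int, fraction: float) -> np.ndarray:
    """Hann lobe over the central ``fraction`` of an n-point centered axis.

    ``fraction >= 1`` means no apodization (flat window over everything).
    """
    if fraction >= 1.0:
        return np.ones(n)
    w = np.zeros(n)
    half = max(1, int(round(n * fraction / 2)))
    c = n // 2
    lo, hi = max(0, c - half), min(n, c + half + 1)
    m = hi - lo
    w[lo:hi] = 0.5 * (1 - np.cos(2 * np.pi * (np.arange(m) + 0.5) / m))
    return w


def lowpass_phase(images: np.ndarray, window_fraction: float = 0.25) -> np.ndarray:
    """Smooth in-plane phase of complex images via an apodized central
    k-space window (Hann over the central ``window_fraction`` per slice)."""
    nd = images.shape[0]
    nz, ny, nx = images.shape[1:]
    win = (_hann_window(ny, window_fraction)[:, None]
           * _hann_window(nx, window_fraction)[None, :])
    ax = (-2, -1)
    out = np.empty((nd, nz, ny, nx))
    for j in range(nd):
        k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(images[j], axes=ax),
                                        axes=ax, norm="ortho"), axes=ax)
        low = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k * win[None], axes=ax),
                                           axes=ax, norm="ortho"), axes=ax)
        out[j] = np.angle(low)
    return out


def estimate_phase_maps(dataset: KSpaceDataset, window_fraction: float = 0.25,
                        tol: float = 1e-6, max_iter: int = 30) -> np.ndarray:
    """MUSE-like smooth phase maps, one per direction (radians).

    Per direction: CG-SENSE reconstruction, then a Hann-apodized central
    k-space window (default: central 25% of the in-plane extent, per slice)
    is inverted to extract a smooth phase.  b=0 volumes get zero phase (no
    diffusion-encoding motion phase).
    """
    init = sense_reconstruct(dataset, phase=None, tol=tol, max_iter=max_iter)
    dwi = ~dataset.scheme.is_b0
    phase = np.zeros((dataset.scheme.n_volumes,) + dataset.grid_shape)
    phase[dwi] = lowpass_phase(init.data[dwi], window_fraction)
    return phase
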