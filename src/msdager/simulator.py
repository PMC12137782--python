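"""Ball-and-stick phantoms and synthetic multi-coil SMS acquisitions.

The generative signal model per voxel is the ball-and-stick model:

    S(b, g) = S0 [ (1 - sum_i f_i) exp(-b d) + sum_i f_i exp(-b d (g.v_i)^2) ]

one isotropic "ball" compartment plus perfectly anisotropic "stick"
compartments with volume fractions f_i, orientations v_i and a single shared
diffusivity d.  Phantoms contain a white-matter interior with a contiguous
crossing-fiber (two-stick) region, a gray-matter rim (ball only), a small
CSF-like core and background; these tissue classes drive the per-tissue GP
hyperparameter fitting downstream and the FA/MD masks recover them.

Acquisition simulation applies the full encoding chain (phase error, coil
sensitivities, unitary FFT, CAIPI mask) and adds i.i.d. complex Gaussian
noise of a given standard deviation per real/imaginary channel to the
sampled k-space entries, so the magnitude images carry Rician noise.  The
SNR convention is SNR = mean white-matter b=0 magnitude / noise SD, i.e.
noise SD 1..16 on a reference intensity of 30 spans SNR 30 down to 1.875.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import KSpaceDataset, ImageSeries, forward
from .sampling import SamplingAssignment
from .scheme import QSpaceScheme

TISSUE_CODES = {"background": 0, "white": 1, "gray": 2, "other": 3}


@dataclass
class PhantomTruth:
    """Ground-truth ball-and-stick parameter maps on a (nz, ny, nx) grid."""

    grid_shape: tuple
    s0_map: np.ndarray  # proton density, arbitrary units
    d_map: np.ndarray  # diffusivity, mm^2/s
    stick_fractions: np.ndarray  # (nz, ny, nx, max_sticks)
    stick_dirs: np.ndarray  # (nz, ny, nx, max_sticks, 3) unit or zero
    tissue_label: np.ndarray  # int codes per TISSUE_CODES

    def __post_init__(self):
        if np.any(self.s0_map < 0):
            raise ValueError("s0 must be nonnegative")
        tissue = self.tissue_label > 0
        if np.any(self.d_map[tissue] <= 0):
            raise ValueError("diffusivity must be positive in tissue")
        if np.any(self.stick_fractions < 0):
            raise ValueError("stick fractions must be nonnegative")
        if np.any(self.stick_fractions.sum(axis=-1) > 1 + 1e-9):
            raise ValueError("stick fractions must sum to <= 1")

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.tissue_label == TISSUE_CODES[name]

    @property
    def n_sticks_map(self) -> np.ndarray:
        return (self.stick_fractions > 0).sum(axis=-1)


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic phantom.

    Diffusivities are typical human-brain values (mm^2/s); stick fractions
    give DTI-equivalent FA ~0.5 in single-fiber and ~0.3 in crossing white
    matter, comfortably separated from the FA<0.2 gray-matter rim.
    """

    grid_shape: tuple = (4, 60, 64)
    crossing_fraction: float = 0.15  # fraction of WM voxels with two sticks
    d_white: float = 1.7e-3
    d_gray: float = 0.85e-3
    d_csf: float = 2.5e-3
    f_single: float = 0.6
    f_crossing: float = 0.3  # per stick, two sticks
    s0_white: float = 1.0
    s0_gray: float = 1.15
    s0_csf: float = 1.4
    rim_fraction: float = 0.82  # inner edge of the gray rim, radius units
    csf_radius: float = 0.18


def ball_and_stick_signal(scheme: QSpaceScheme, s0: float, d: float,
                          sticks) -> np.ndarray:
    """Evaluate the ball-and-stick signal for every volume of ``scheme``.

    ``sticks`` is a sequence of (fraction, orientation) pairs; validates
    fractions in [0, 1] summing to <= 1 and unit orientations.
    """
    if d <= 0:
        raise ValueError("diffusivity must be positive")
    fracs, dirs = [], []
    for f, v in sticks:
        if f < 0:
            raise ValueError("negative stick fraction")
        v = np.asarray(v, dtype=float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("stick orientation must be a unit vector")
        fracs.append(f)
        dirs.append(v)
    fracs = np.asarray(fracs) if fracs else np.zeros(0)
    if fracs.sum() > 1 + 1e-9:
        raise ValueError("stick fractions sum to more than 1")
    b = scheme.bvals
    sig = (1.0 - fracs.sum()) * np.exp(-b * d)
    for f, v in zip(fracs, dirs):
        proj = scheme.bvecs @ v
        sig = sig + f * np.exp(-b * d * proj ** 2)
    return s0 * sig


def phantom_signal(truth: PhantomTruth, scheme: QSpaceScheme) -> ImageSeries:
    """Noise-free signal images for every volume (vectorized over voxels)."""
    b = scheme.bvals  # (Nd,)
    s0 = truth.s0_map[None]  # (1, nz, ny, nx)
    d = truth.d_map[None]
    bd = b[:, None, None, None] * d
    f = truth.stick_fractions  # (nz, ny, nx, ns)
    ball = (1.0 - f.sum(axis=-1))[None] * np.exp(-bd)
    sig = ball
    for s in range(f.shape[-1]):
        proj = np.einsum("dk,zyxk->dzyx", scheme.bvecs, truth.stick_dirs[..., s, :])
        sig = sig + f[None, ..., s] * np.exp(-bd * proj ** 2)
    data = (s0 * sig).astype(complex)
    data[:, truth.tissue_label == 0] = 0.0
    return ImageSeries(data, scheme)


def make_phantom(spec: PhantomSpec = None, seed: int = 0) -> PhantomTruth:
    """Deterministic-for-seed multi-slice phantom.

    An elliptical "brain" per slice: gray-matter rim, white-matter interior
    with gently curving fibers, a contiguous crossing-fiber patch sized to
    ``crossing_fraction`` of white matter, and a CSF-like core.
    """
    spec = spec or PhantomSpec()
    nz, ny, nx = spec.grid_shape
    if nz < 1 or ny < 16 or nx < 16:
        raise ValueError("grid must be at least 16x16 in-plane with >=1 slice")
    rng = np.random.default_rng(seed)
    y, x = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")

    s0 = np.zeros(spec.grid_shape)
    d = np.zeros(spec.grid_shape)
    label = np.zeros(spec.grid_shape, dtype=int)
    max_sticks = 2
    fr = np.zeros(spec.grid_shape + (max_sticks,))
    dv = np.zeros(spec.grid_shape + (max_sticks, 3))

    for z in range(nz):
        # slice-dependent ellipse emulates through-slice anatomy change
        ay = 0.88 - 0.04 * abs(z - (nz - 1) / 2)
        ax_ = 0.78 - 0.03 * abs(z - (nz - 1) / 2)
        r = np.sqrt((y / ay) ** 2 + (x / ax_) ** 2)
        brain = r < 1.0
        gray = brain & (r >= spec.rim_fraction)
        csf = r < spec.csf_radius
        white = brain & ~gray & ~csf

        label[z][gray] = TISSUE_CODES["gray"]
        label[z][white] = TISSUE_CODES["white"]
        label[z][csf] = TISSUE_CODES["other"]
        s0[z][gray], s0[z][white], s0[z][csf] = spec.s0_gray, spec.s0_white, spec.s0_csf
        d[z][gray], d[z][white], d[z][csf] = spec.d_gray, spec.d_white, spec.d_csf

        # curving single-fiber field: mostly left-right, bending with y
        alpha = 0.5 * y + 0.15 * np.sin(2.5 * x)
        v1 = np.stack([np.zeros_like(x), np.sin(alpha), np.cos(alpha)], axis=-1)
        # crossing patch: the WM voxels nearest a seeded center
        wm_idx = np.argwhere(white)
        n_cross = int(round(spec.crossing_fraction * len(wm_idx)))
        cross = np.zeros_like(white)
        if n_cross > 0 and len(wm_idx):
            cy = rng.uniform(-0.3, 0.3)
            cx = rng.uniform(-0.3, 0.3)
            dist = (y[white] - cy) ** 2 + (x[white] - cx) ** 2
            sel = np.argsort(dist)[:n_cross]
            cross_idx = wm_idx[sel]
            cross[tuple(cross_idx.T)] = True
        single = white & ~cross

        fr[z][single, 0] = spec.f_single
        dv[z][single, 0, :] = v1[single]
        fr[z][cross, 0] = spec.f_crossing
        fr[z][cross, 1] = spec.f_crossing
        dv[z][cross, 0, :] = v1[cross]
        # second population: in-plane, perpendicular-ish to the first
        v2 = np.stack([np.zeros_like(x), np.cos(alpha), -np.sin(alpha)], axis=-1)
        dv[z][cross, 1, :] = v2[cross]

    return PhantomTruth(spec.grid_shape, s0, d, fr, dv, label)


def make_coil_sensitivities(grid_shape, n_coils: int = 8, seed: int = 0,
                            support: np.ndarray | None = None) -> np.ndarray:
    """Smooth complex coil maps: Gaussian lobes ringed around the FOV.

    Eight coils by default (head-coil layout).  Each coil has a smooth
    low-order phase; maps are normalized to unit sum-of-squares magnitude so
    coil combination preserves intensity over the object.
    """
    nz, ny, nx = grid_shape
    rng = np.random.default_rng(seed)
    y, x = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    z = np.linspace(-0.5, 0.5, nz)
    maps = np.empty((n_coils, nz, ny, nx), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.05)
        cy, cx = 1.25 * np.sin(ang), 1.25 * np.cos(ang)
        width = 0.9 + rng.normal(0, 0.05)
        mag = np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * width ** 2))
        ph = (rng.uniform(-np.pi, np.pi)
              + rng.normal(0, 0.8) * y + rng.normal(0, 0.8) * x
              + rng.normal(0, 0.3) * x * y)
        lobe = mag * np.exp(1j * ph)
        for k in range(nz):
            maps[c, k] = lobe * (1.0 + 0.05 * z[k] * np.cos(ang))
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= sos[None]
    if support is not None and not np.any(np.abs(maps[:, support]) > 0):
        raise ValueError("sensitivities vanish over the object support")
    return maps


def make_phase_errors(scheme: QSpaceScheme, grid_shape, seed: int = 0,
                      linear_scale: float = 1.2, quad_scale: float = 0.4) -> np.ndarray:
    """Smooth per-direction phase-error maps (radians), zero for b=0.

    Low-order in-plane polynomials with random coefficients per direction and
    slice, emulating shot-to-shot motion-induced phase in diffusion EPI.
    """
    nz, ny, nx = grid_shape
    rng = np.random.default_rng(seed)
    y, x = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    phase = np.zeros((scheme.n_volumes, nz, ny, nx))
    for j in range(scheme.n_volumes):
        if scheme.is_b0[j]:
            continue
        for z in range(nz):
            c = rng.normal(0, 1, 6)
            phase[j, z] = (c[0] * np.pi / 2
                           + linear_scale * (c[1] * y + c[2] * x)
                           + quad_scale * (c[3] * y * x + c[4] * y ** 2 + c[5] * x ** 2))
    return phase


def simulate_acquisition(truth: PhantomTruth, scheme: QSpaceScheme,
                         sens: np.ndarray, assignment: SamplingAssignment,
                         noise_sd: float = 0.0,
                         phase: np.ndarray | None = None,
                         seed: int = 0) -> KSpaceDataset:
    """Noisy undersampled multi-coil k-space for every volume.

    d_j = Omega_j (F S P_j u_j + n),  n ~ CN(0, 2*noise_sd^2) i.i.d.
    (noise_sd per real/imaginary channel).  Unsampled entries are exactly
    zero.
    """
    if sens.shape[1:] != truth.grid_shape:
        raise ValueError("coil map grid does not match phantom grid")
    if assignment.indices.size != scheme.n_volumes:
        raise ValueError("sampling assignment does not match scheme")
    images = phantom_signal(truth, scheme)
    nz, ny, nx = truth.grid_shape
    nd, nc = scheme.n_volumes, sens.shape[0]
    rng = np.random.default_rng(seed)
    data = np.zeros((nd, nc, nz, ny, nx), dtype=complex)
    masks = np.zeros((nd, nz, ny), dtype=bool)
    for j in range(nd):
        masks[j] = assignment.pattern_for(j).mask(ny, nz)
        ph = phase[j] if phase is not None else None
        k = forward(images.data[j], sens, masks[j], ph)
        if noise_sd > 0:
            noise = rng.normal(0, noise_sd, k.shape) + 1j * rng.normal(0, noise_sd, k.shape)
            k = k + noise * masks[j][None, :, :, None]
        data[j] = k
    s0_ref = float(truth.s0_map[truth.tissue_mask("white")].mean()) if \
        np.any(truth.tissue_mask("white")) else float(truth.s0_map.max())
    meta = {"noise_sd": float(noise_sd), "s0_ref": s0_ref,
            "snr": (s0_ref / noise_sd) if noise_sd > 0 else np.inf, "seed": int(seed)}
    return KSpaceDataset(data, masks, sens, scheme, assignment, meta)
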