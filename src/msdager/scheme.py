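"""Diffusion sampling schemes: b-values, gradient directions, shell structure.

A scheme is the q-space side of an acquisition: one (b, g) pair per volume.
Volumes are grouped into shells by b-value (tolerance 50 s/mm^2, the usual
scanner rounding slack); b=0 volumes form their own shell and carry a zero
gradient vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SHELL_TOL = 50.0  # s/mm^2; b-values closer than this belong to one shell


@dataclass(frozen=True)
class QSpaceScheme:
    """b-values and unit gradient directions for a set of DWI volumes.

    Parameters
    ----------
    bvals : (Nd,) float array, s/mm^2
    bvecs : (Nd, 3) float array, unit vectors (zero allowed where b == 0)
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size) and bvals.size != 3:
            bvecs = bvecs.T
        bvecs = bvecs.reshape(bvals.size, 3)
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > SHELL_TOL
        if np.any(norms[dwi] < 1e-6):
            raise ValueError("zero gradient vector on a diffusion-weighted volume")
        unit = bvecs.copy()
        unit[dwi] = bvecs[dwi] / norms[dwi, None]
        unit[~dwi & (norms < 1e-6)] = 0.0
        nz = ~dwi & (norms >= 1e-6)
        unit[nz] = bvecs[nz] / norms[nz, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", unit)
        if self.shell_ids is None:
            object.__setattr__(self, "shell_ids", _group_shells(bvals))
        else:
            object.__setattr__(self, "shell_ids", np.asarray(self.shell_ids, dtype=int).ravel())

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def shells(self) -> np.ndarray:
        """Representative b-value per shell id, ascending."""
        ids = np.unique(self.shell_ids)
        return np.array([self.bvals[self.shell_ids == i].mean() for i in ids])

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= SHELL_TOL

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_b0)

    def subset(self, indices) -> "QSpaceScheme":
        idx = np.asarray(indices)
        return QSpaceScheme(self.bvals[idx], self.bvecs[idx], self.shell_ids[idx])


def _group_shells(bvals: np.ndarray) -> np.ndarray:
    """Assign consecutive shell ids (ascending b) with SHELL_TOL clustering."""
    order = np.argsort(bvals)
    ids = np.empty(bvals.size, dtype=int)
    current, ref = 0, None
    for i in order:
        if ref is None or bvals[i] - ref > SHELL_TOL:
            if ref is not None:
                current += 1
            ref = bvals[i]
        ids[i] = current
    return ids


def read_scheme(bval_path, bvec_path) -> QSpaceScheme:
    """Read an FSL-convention bval/bvec pair.

    bvals: one whitespace-separated row; bvecs: three rows (x, y, z), one
    column per volume. Near-unit vectors are silently normalized.
    """
    try:
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    except ValueError as e:
        raise ValueError(f"could not parse bval file {bval_path}: {e}") from e
    try:
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except ValueError as e:
        raise ValueError(f"could not parse bvec file {bvec_path}: {e}") from e
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bval/bvec count mismatch: {bvals.size} b-values vs {bvecs.shape} vectors"
        )
    return QSpaceScheme(bvals, bvecs)


def write_scheme(scheme: QSpaceScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.6f")


def two_shell_scheme(n_per_shell: int, b_low: float = 1000.0, b_high: float = 2000.0,
                     n_b0: int = 1, seed: int = 0) -> QSpaceScheme:
    """Staggered two-shell scheme with quasi-uniform hemisphere coverage.

    Directions come from a Fibonacci spiral on the hemisphere (antipodal
    symmetry makes the hemisphere sufficient); the two shells interleave
    along the spiral so each shell is itself near-uniform, matching the
    staggered multi-shell designs used in practice.
    """
    n = 2 * n_per_shell
    dirs = fibonacci_hemisphere(n, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.where(np.arange(n) % 2 == 0, b_low, b_high)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return QSpaceScheme(bvals, bvecs)


def fibonacci_hemisphere(n: int, seed: int = 0) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    z = i / n  # cos(polar) in (0, 1): upper hemisphere
    phi = np.pi * (1 + 5 ** 0.5) * i + 2 * np.pi * (seed % 997) / 997
    s = np.sqrt(1 - z ** 2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
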