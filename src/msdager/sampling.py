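"""Blipped-CAIPI k-space undersampling patterns and their assignment in q-space.

Simultaneous-multislice EPI with blipped-CAIPI is treated as a 3D encoding
problem over the SMS simultaneously excited slices: the slice dimension
becomes a kz (partition) axis of size SMS with step delta_kz = 1/FOVz_SMS.
One pattern keeps every R-th ky line, and the kz index blips by one per
acquired line, so the R*SMS patterns obtained by offsetting (ky_shift,
kz_shift) tile the full (ky, kz) grid exactly once each.

Assigning different patterns to q-space neighbors makes their aliasing
artifacts incoherent, which is what lets a joint k-q reconstruction pull
complementary information from the neighborhood.  The assignment here is a
greedy maximum-diversity heuristic with random restarts; the achieved
diversity score is reported so a design can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import QSpaceScheme


def _default_blip(R: int, SMS: int) -> int:
    """kz increment per acquired ky line.

    A blip of R gives the standard FOVy/SMS inter-slice image shift (e.g.
    FOVy/3 for R=2, SMS=3); when gcd(R, SMS) != 1 that blip would not cycle
    through all partitions, so fall back to the smallest coprime step.
    """
    if SMS == 1:
        return 0
    b = R % SMS
    while b == 0 or np.gcd(b, SMS) != 1:
        b += 1
    return b


@dataclass(frozen=True)
class SamplingPattern:
    """One CAIPI undersampling pattern on an (Nky, Nkz=SMS) grid."""

    R_inplane: int
    SMS: int
    ky_shift: int
    kz_shift: int
    partial_fourier: float = 1.0
    delta_kz: float | None = None  # 1/FOVz_SMS, metadata only
    blip: int | None = None

    def __post_init__(self):
        if not (0 <= self.ky_shift < self.R_inplane):
            raise ValueError("ky_shift out of range [0, R)")
        if not (0 <= self.kz_shift < self.SMS):
            raise ValueError("kz_shift out of range [0, SMS)")
        if self.partial_fourier not in (1.0, 7 / 8, 6 / 8, 0.875, 0.75):
            raise ValueError("partial_fourier must be one of 1, 7/8, 6/8")
        if self.blip is None:
            object.__setattr__(self, "blip", _default_blip(self.R_inplane, self.SMS))

    @property
    def interslice_shift_fraction(self) -> float:
        """In-plane image shift between adjacent slice replicas, in FOVy units."""
        if self.SMS == 1:
            return 0.0
        return self.blip / (self.R_inplane * self.SMS)

    def mask(self, n_ky: int, n_kz: int | None = None) -> np.ndarray:
        """Boolean (n_kz, n_ky) mask of sampled points.

        Sampled lines: ky ≡ ky_shift (mod R); the j-th acquired line samples
        kz = (kz_shift + j*blip) mod SMS.  Partial Fourier keeps only the
        first ceil(pf * n_ky) ky indices (asymmetric coverage, zero-filled
        elsewhere).
        """
        n_kz = self.SMS if n_kz is None else n_kz
        if n_kz % self.SMS:
            raise ValueError("kz grid must be a multiple of SMS")
        m = np.zeros((n_kz, n_ky), dtype=bool)
        ky_max = int(np.ceil(self.partial_fourier * n_ky))
        lines = np.arange(self.ky_shift, ky_max, self.R_inplane)
        kz = (self.kz_shift + self.blip * np.arange(lines.size)) % self.SMS
        # replicate across kz super-periods when n_kz > SMS
        for rep in range(n_kz // self.SMS):
            m[kz + rep * self.SMS, lines] = True
        return m

    def n_sampled(self, n_ky: int, n_kz: int | None = None) -> int:
        return int(self.mask(n_ky, n_kz).sum())


def enumerate_patterns(R: int, SMS: int, partial_fourier: float = 1.0,
                       delta_kz: float | None = None) -> list[SamplingPattern]:
    """All R*SMS distinct (ky_shift, kz_shift) CAIPI patterns."""
    if R < 1 or SMS < 1:
        raise ValueError("R and SMS must be >= 1")
    return [SamplingPattern(R, SMS, ky, kz, partial_fourier, delta_kz)
            for ky in range(R) for kz in range(SMS)]


@dataclass
class SamplingAssignment:
    """One pattern per q-space volume."""

    patterns: list[SamplingPattern]
    indices: np.ndarray  # (Nd,) index into ``patterns`` per volume
    diversity_score: float = field(default=np.nan)

    def pattern_for(self, volume: int) -> SamplingPattern:
        return self.patterns[int(self.indices[volume])]

    def to_dict(self) -> dict:
        return {
            "R": self.patterns[0].R_inplane, "SMS": self.patterns[0].SMS,
            "partial_fourier": self.patterns[0].partial_fourier,
            "assignment": [{"ky_shift": p.ky_shift, "kz_shift": p.kz_shift}
                           for p in (self.patterns[i] for i in self.indices)],
            "diversity_score": float(self.diversity_score),
        }


def _neighborhoods(scheme: QSpaceScheme, angle: float) -> list[np.ndarray]:
    """Antipodal q-space neighborhoods across all shells (self included).

    b=0 volumes have no direction; each is its own neighborhood and never
    joins a DWI neighborhood.
    """
    g = scheme.bvecs
    nd = scheme.n_volumes
    b0 = scheme.is_b0
    dot = np.abs(g @ g.T)
    theta = np.arccos(np.clip(dot, -1.0, 1.0))
    theta[b0, :] = np.inf
    theta[:, b0] = np.inf
    np.fill_diagonal(theta, 0.0)
    return [np.flatnonzero(theta[i] < angle) for i in range(nd)]


def diversity_score(indices: np.ndarray, neighborhoods, n_patterns: int) -> float:
    """Mean over volumes of (#distinct patterns in nbhd) / min(|nbhd|, |family|)."""
    scores = [len(set(indices[nb].tolist())) / min(len(nb), n_patterns)
              for nb in neighborhoods]
    return float(np.mean(scores))


def assign_patterns(scheme: QSpaceScheme, family: list[SamplingPattern],
                    neighborhood_angle: float = np.deg2rad(30),
                    seed: int = 0, n_restarts: int = 8) -> SamplingAssignment:
    """Greedy max-diversity assignment of patterns to q-space volumes.

    Volumes are visited in a random order per restart; each is given the
    pattern least used among its already-assigned q-space neighbors (ties
    broken by global usage, then pattern index).  The restart with the best
    diversity score wins; deterministic for a fixed seed.
    """
    if not family:
        raise ValueError("pattern family is empty")
    scheme_dwi = scheme
    nbhds = _neighborhoods(scheme_dwi, neighborhood_angle)
    n_pat, nd = len(family), scheme_dwi.n_volumes
    if max(len(nb) for nb in nbhds) > n_pat:
        import warnings
        warnings.warn("q-space neighborhood larger than pattern family; "
                      "pattern reuse within neighborhoods is unavoidable")
    rng = np.random.default_rng(seed)
    best_idx, best_score = None, -1.0
    for _ in range(max(1, n_restarts)):
        order = rng.permutation(nd)
        idx = np.full(nd, -1, dtype=int)
        usage = np.zeros(n_pat, dtype=int)
        for v in order:
            local = np.zeros(n_pat, dtype=int)
            for nb in nbhds[v]:
                if idx[nb] >= 0:
                    local[idx[nb]] += 1
            cost = local * n_pat * nd + usage  # lexicographic: local, then global
            idx[v] = int(np.argmin(cost))
            usage[idx[v]] += 1
        score = diversity_score(idx, nbhds, n_pat)
        if score > best_score:
            best_idx, best_score = idx, score
    return SamplingAssignment(patterns=list(family), indices=best_idx,
                              diversity_score=best_score)


def random_assignment(scheme: QSpaceScheme, family: list[SamplingPattern],
                      neighborhood_angle: float = np.deg2rad(30),
                      seed: int = 0) -> SamplingAssignment:
    """Uniform random baseline for comparing diversity scores."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(family), scheme.n_volumes)
    nbhds = _neighborhoods(scheme, neighborhood_angle)
    return SamplingAssignment(patterns=list(family), indices=idx,
                              diversity_score=diversity_score(idx, nbhds, len(family)))
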