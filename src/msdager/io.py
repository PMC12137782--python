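"""File I/O: k-space containers (HDF5), NIfTI image series, JSON configs.

Complex k-space and coil data live in HDF5 with named arrays and documented
axis order; NIfTI holds only magnitude images (direction as the 4th axis,
grid stored as (nx, ny, nz) per NIfTI convention while the package works in
(nz, ny, nx)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .encoding import ImageSeries, KSpaceDataset
from .sampling import SamplingAssignment, SamplingPattern
from .scheme import QSpaceScheme, read_scheme, write_scheme

AXIS_ORDER = "volume, coil, kz, ky, kx"


def save_kspace(dataset: KSpaceDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["axis_order"] = AXIS_ORDER
        f.create_dataset("kspace", data=dataset.data, compression="gzip")
        f.create_dataset("pattern", data=dataset.masks.astype(np.uint8),
                         compression="gzip")
        f.create_dataset("sens", data=dataset.sens, compression="gzip")
        f.create_dataset("bvals", data=dataset.scheme.bvals)
        f.create_dataset("bvecs", data=dataset.scheme.bvecs)
        if dataset.assignment is not None:
            f.attrs["assignment"] = json.dumps(dataset.assignment.to_dict())
        f.attrs["meta"] = json.dumps(dataset.meta)


def load_kspace(path) -> KSpaceDataset:
    with h5py.File(path, "r") as f:
        data = f["kspace"][...]
        masks = f["pattern"][...].astype(bool)
        sens = f["sens"][...]
        scheme = QSpaceScheme(f["bvals"][...], f["bvecs"][...])
        assignment = None
        if "assignment" in f.attrs:
            assignment = assignment_from_dict(json.loads(f.attrs["assignment"]))
        meta = json.loads(f.attrs.get("meta", "{}"))
    return KSpaceDataset(data, masks, sens, scheme, assignment, meta)


def assignment_from_dict(d: dict) -> SamplingAssignment:
    family = [SamplingPattern(d["R"], d["SMS"], ky, kz, d.get("partial_fourier", 1.0))
              for ky in range(d["R"]) for kz in range(d["SMS"])]
    lut = {(p.ky_shift, p.kz_shift): i for i, p in enumerate(family)}
    idx = np.array([lut[(e["ky_shift"], e["kz_shift"])] for e in d["assignment"]])
    return SamplingAssignment(family, idx, d.get("diversity_score", np.nan))


def write_dwi(series: ImageSeries, path, affine: np.ndarray | None = None,
              sidecars: bool = True) -> None:
    """Write magnitude images as 4D NIfTI (+ FSL bval/bvec sidecars)."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    mag = series.magnitude()  # (Nd, nz, ny, nx)
    vol = np.ascontiguousarray(np.transpose(mag, (3, 2, 1, 0)))  # x, y, z, dir
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
    if sidecars:
        stem = str(path)
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        write_scheme(series.scheme, stem + ".bval", stem + ".bvec")


def read_dwi(path, bval_path=None, bvec_path=None) -> ImageSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    data = np.transpose(vol, (3, 2, 1, 0)).astype(complex)  # dir, z, y, x
    if bval_path is None:
        stem = str(path)
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        bval_path, bvec_path = stem + ".bval", stem + ".bvec"
    scheme = read_scheme(bval_path, bvec_path)
    return ImageSeries(data, scheme)


# ---------------------------------------------------------------------------
# run configuration

_ALLOWED = {
    "simulator": {"grid", "n_per_shell", "b_low", "b_high", "n_b0", "snr",
                  "crossing_fraction", "n_coils", "phase_errors"},
    "sampling": {"R", "SMS", "partial_fourier", "neighborhood_deg", "n_restarts"},
    "reconstruction": {"method", "outer_iters", "inner_tol", "inner_max_iter",
                       "use_vst", "tissue_hyper", "phase_window", "refine_phase",
                       "max_fit_voxels", "fit_maxiter"},
    "evaluation": {"bin_width_deg", "ratio_statistic"},
}

_DEFAULTS = {
    "simulator": {"grid": [4, 60, 64], "n_per_shell": 18, "b_low": 1000.0,
                  "b_high": 2000.0, "n_b0": 1, "snr": 20.0,
                  "crossing_fraction": 0.15, "n_coils": 8, "phase_errors": True},
    "sampling": {"R": 3, "SMS": 4, "partial_fourier": 1.0,
                 "neighborhood_deg": 30.0, "n_restarts": 8},
    "reconstruction": {"method": "ms-dager", "outer_iters": 3, "inner_tol": 1e-8,
                       "inner_max_iter": 400, "use_vst": True, "tissue_hyper": True,
                       "phase_window": 0.25, "refine_phase": True,
                       "max_fit_voxels": 2000, "fit_maxiter": 150},
    "evaluation": {"bin_width_deg": 5.0, "ratio_statistic": "median"},
}


@dataclass
class RunConfig:
    """Nested pipeline configuration; unknown keys are rejected."""

    simulator: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    reconstruction: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for block, allowed in _ALLOWED.items():
            user = getattr(self, block)
            unknown = set(user) - allowed
            if unknown:
                raise ValueError(f"unknown keys in '{block}' config: {sorted(unknown)}")
            merged = {**_DEFAULTS[block], **user}
            setattr(self, block, merged)

    def to_dict(self) -> dict:
        return {"simulator": self.simulator, "sampling": self.sampling,
                "reconstruction": self.reconstruction,
                "evaluation": self.evaluation, "seed": self.seed}

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - {"simulator", "sampling", "reconstruction",
                              "evaluation", "seed"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
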