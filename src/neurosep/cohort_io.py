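"""Volume and cohort I/O plus the in-scope preprocessing steps.

Volumes travel as NIfTI-1 files (via :mod:`nibabel`); cohort metadata is a
tab-separated table.  The preprocessing implemented here is the tail of a
standard SPM-style pipeline: Gaussian smoothing (functional volumes) and
per-volume z-normalization (both modalities).  Motion correction,
co-registration and template normalization are assumed to have been done
by external tools.

Voxel ordering convention: whenever a 3D volume is flattened against a
mask, voxels are taken in C order of the (X, Y, Z) array (last axis
fastest).  Every matrix column index in the package refers to this order,
so spatial maps and mixing matrices are reproducible across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "FWHM_PER_SIGMA",
    "Volume3D",
    "BoldSeries",
    "CohortTable",
    "DegenerateInputError",
    "fwhm_to_sigma",
    "preprocess_volume",
    "z_normalize",
    "vectorize_series",
    "scatter_to_mask",
    "load_volume",
    "save_volume",
    "load_mask",
    "load_cohort",
]

#: fwhm = 2 * sqrt(2 * ln 2) * sigma for a Gaussian kernel.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

VALID_LABELS = ("case", "control")
VALID_SPLITS = ("train", "holdout")
COHORT_COLUMNS = [
    "subject_id",
    "label",
    "site",
    "split",
    "structural_path",
    "functional_path",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but informationless
    (constant volume, empty mask, rank-0 data...)."""


@dataclass
class Volume3D:
    """A 3D image with voxel geometry.

    Parameters
    ----------
    intensities : (X, Y, Z) float array
    voxel_size : mm extent of one voxel along each axis
    affine : 4x4 voxel-to-world transform
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a non-empty 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class BoldSeries:
    """One subject's functional data as a T x V matrix over a voxel mask."""

    data: np.ndarray
    mask: np.ndarray
    t_common: int
    subject_id: str = ""
    site: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be T x V")
        if self.t_common < 2 or self.data.shape[0] != self.t_common:
            raise ValueError("need T = t_common >= 2")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("V must equal the number of true mask voxels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortTable:
    """Validated cohort metadata (one row per subject)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        dup = self.frame["subject_id"].duplicated()
        if dup.any():
            raise ValueError(
                "duplicate subject_id: "
                + ", ".join(self.frame.loc[dup, "subject_id"].astype(str))
            )
        for col, valid in (("label", VALID_LABELS), ("split", VALID_SPLITS)):
            bad = ~self.frame[col].isin(valid)
            if bad.any():
                row = self.frame.index[bad][0]
                raise ValueError(
                    f"unknown {col} {self.frame.loc[row, col]!r} in row "
                    f"{row} (subject {self.frame.loc[row, 'subject_id']!r})"
                )
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, split: str) -> "CohortTable":
        return CohortTable(self.frame[self.frame["split"] == split].copy())

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def sites(self) -> np.ndarray:
        return self.frame["site"].to_numpy()


def fwhm_to_sigma(fwhm_mm: float, voxel_mm: float = 1.0) -> float:
    """Kernel width in voxels for a smoothing FWHM given in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    return fwhm_mm / (FWHM_PER_SIGMA * voxel_mm)


def z_normalize(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    if sd == 0:
        raise DegenerateInputError("constant-intensity volume has no z-score")
    return (arr - arr.mean()) / sd


def preprocess_volume(v: Volume3D, fwhm_mm: float = 8.0) -> Volume3D:
    """Gaussian-smooth (if ``fwhm_mm > 0``) then z-normalize a volume.

    The kernel sigma is fwhm / (2 sqrt(2 ln 2)) converted to voxels per
    axis using the volume's voxel size.  Z-normalization maps the whole
    volume to mean 0, standard deviation 1.
    """
    arr = v.intensities
    if fwhm_mm > 0:
        sigmas = [fwhm_to_sigma(fwhm_mm, vs) for vs in v.voxel_size]
        arr = gaussian_filter(arr, sigma=sigmas, mode="constant")
    return Volume3D(z_normalize(arr), voxel_size=v.voxel_size, affine=v.affine)


def smooth_volume(v: Volume3D, fwhm_mm: float) -> Volume3D:
    """Gaussian smoothing only (no normalization)."""
    if fwhm_mm == 0:
        return Volume3D(v.intensities.copy(), v.voxel_size, v.affine)
    sigmas = [fwhm_to_sigma(fwhm_mm, vs) for vs in v.voxel_size]
    return Volume3D(
        gaussian_filter(v.intensities, sigma=sigmas, mode="constant"),
        v.voxel_size,
        v.affine,
    )


def vectorize_series(
    frames: Sequence[Volume3D],
    mask: np.ndarray,
    t_common: int,
    resample: str = "truncate",
    subject_id: str = "",
    site: str = "",
    label: str = "",
) -> BoldSeries:
    """Stack masked frames into a T x V matrix (T = ``t_common``).

    Column j holds the j-th true mask voxel in C order.  Series longer
    than ``t_common`` are truncated (default) or linearly resampled onto
    ``t_common`` equally spaced time points (``resample='linear'``).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("mask selects no voxels")
    if t_common < 2:
        raise ValueError("t_common must be >= 2")
    if t_common > len(frames):
        raise ValueError("t_common exceeds the number of frames")
    for f in frames:
        if f.shape != mask.shape:
            raise ValueError("frame/mask shape mismatch")
    flat_mask = mask.reshape(-1)  # C order
    rows = np.stack([f.intensities.reshape(-1)[flat_mask] for f in frames])
    if len(frames) != t_common:
        if resample == "truncate":
            rows = rows[:t_common]
        elif resample == "linear":
            t_old = np.arange(len(frames), dtype=float)
            t_new = np.linspace(0.0, len(frames) - 1.0, t_common)
            rows = np.stack([np.interp(t_new, t_old, col) for col in rows.T], axis=1)
        else:
            raise ValueError(f"unknown resample mode {resample!r}")
    return BoldSeries(
        data=rows,
        mask=mask,
        t_common=t_common,
        subject_id=subject_id,
        site=site,
        label=label,
    )


def scatter_to_mask(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Inverse of masking: place a length-V vector back into the 3D grid."""
    mask = np.asarray(mask, dtype=bool)
    out = np.full(mask.shape, fill, dtype=float).reshape(-1)
    out[mask.reshape(-1)] = values
    return out.reshape(mask.shape)


def load_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, voxel_size=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))


def load_series(path: str | Path) -> list[Volume3D]:
    """Load a 4D NIfTI as a list of per-timepoint volumes."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    vs = tuple(float(z) for z in zooms)
    aff = np.asarray(img.affine)
    return [Volume3D(data[..., t], voxel_size=vs, affine=aff) for t in range(data.shape[-1])]


def save_volume(v: Volume3D, path: str | Path) -> None:
    affine = v.affine if v.affine is not None else np.diag([*v.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(v.intensities.astype(np.float32), affine), str(path))


def save_series(frames: Sequence[Volume3D], path: str | Path) -> None:
    data = np.stack([f.intensities for f in frames], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, frames[0].affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) != 0


def load_cohort(table_path: str | Path, check_files: bool = True) -> CohortTable:
    """Read and validate a cohort TSV.

    The header must be exactly ``subject_id label site split
    structural_path functional_path``; paths are resolved relative to the
    table's directory and must exist when ``check_files`` is set.
    """
    table_path = Path(table_path)
    frame = pd.read_csv(table_path, sep="\t", dtype=str)
    if list(frame.columns) != COHORT_COLUMNS:
        raise ValueError(
            f"cohort header must be {COHORT_COLUMNS}, got {list(frame.columns)}"
        )
    base = table_path.parent
    if check_files:
        for _, row in frame.iterrows():
            for col in ("structural_path", "functional_path"):
                p = Path(row[col])
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(
                        f"subject {row['subject_id']!r}: missing {col} {row[col]!r}"
                    )
    return CohortTable(frame)
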