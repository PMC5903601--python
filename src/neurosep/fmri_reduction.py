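"""Two-step PCA for multi-subject functional data and back-reconstruction.

Each subject's T x V series is first reduced along time to T_red rows
capturing a target variance fraction; the reduced matrices are stacked
(temporal concatenation) and a second, group-level PCA yields the K x V
representative matrix handed to source separation.  Given group spatial
maps S and a group mixing matrix A (K x C), subject time courses are
recovered by inverting the two reductions:

    A_i = U_i^+ (F^+)_i A,     X^i ~ A_i S

where (F^+)_i is the subject-i row block of the pseudo-inverse of the
group reduction operator.  Because both reduction operators have
orthonormal rows this inversion is exact on the retained subspace, so on
noiseless data of exact rank the round trip reproduces each subject's
(row-centered) matrix to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .cohort_io import BoldSeries, DegenerateInputError

__all__ = [
    "SubjectReduction",
    "GroupReduction",
    "RepresentativeMatrix",
    "SubjectTimecourses",
    "subject_pca",
    "group_pca",
    "back_reconstruct",
    "timecourses_by_regression",
    "fmri_feature_vector",
    "save_reductions",
    "load_reductions",
]


@dataclass
class SubjectReduction:
    """Temporal reduction operator for one subject."""

    U: np.ndarray  # T_red x T, orthonormal rows
    eigenvalues: np.ndarray  # all T eigenvalues, descending
    t_red: int
    var_captured: float
    row_means: np.ndarray  # per-timepoint mean removed before PCA

    def __post_init__(self) -> None:
        if self.U.shape[0] != self.t_red:
            raise ValueError("U must have t_red rows")


@dataclass
class GroupReduction:
    """Group-level reduction operator over concatenated subject blocks."""

    F: np.ndarray  # K x sum(T_red_i), orthonormal rows
    blocks: list[tuple[int, int]]  # per-subject column ranges of F
    K: int
    var_captured: float
    eigenvalues: np.ndarray
    row_means: np.ndarray

    def __post_init__(self) -> None:
        if self.F.shape[0] != self.K:
            raise ValueError("F must have K rows")
        stops = [b[1] for b in self.blocks]
        starts = [b[0] for b in self.blocks]
        if starts[0] != 0 or stops[-1] != self.F.shape[1] or any(
            a != b for a, b in zip(stops[:-1], starts[1:])
        ):
            raise ValueError("blocks must partition the columns in subject order")


@dataclass
class RepresentativeMatrix:
    """K x V matrix summarizing the whole cohort."""

    X: np.ndarray
    group: GroupReduction
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.group.K:
            raise ValueError("X must have K rows")

    @property
    def K(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


@dataclass
class SubjectTimecourses:
    """Estimated T x C component time courses for one subject."""

    A: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or not np.all(np.isfinite(self.A)):
            raise ValueError("A must be a finite T x C matrix")

    @property
    def t_points(self) -> int:
        return self.A.shape[0]

    @property
    def n_components(self) -> int:
        return self.A.shape[1]


def _pca_rows(data: np.ndarray, var_frac: float | None, k_fixed: int | None):
    """PCA over rows: eigendecompose the row-centered Gram matrix.

    Returns (projection P, Y = P @ centered, eigenvalues, retained,
    var_captured, row_means).  Working on the T x T Gram matrix keeps
    the decomposition tractable when V >> T.
    """
    data = np.asarray(data, dtype=float)
    row_means = data.mean(axis=1)
    centered = data - row_means[:, None]
    gram = centered @ centered.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise DegenerateInputError("rank-0 data: nothing to reduce")
    if k_fixed is not None:
        keep = min(k_fixed, len(evals))
    else:
        frac = np.cumsum(evals) / total
        keep = int(np.searchsorted(frac, var_frac - 1e-12) + 1)
        keep = min(keep, len(evals))
    P = evecs[:, :keep].T  # keep x T, orthonormal rows
    var_captured = float(evals[:keep].sum() / total)
    return P, P @ centered, evals, keep, var_captured, row_means


def subject_pca(
    b: BoldSeries | np.ndarray, var_frac: float = 0.99
) -> tuple[np.ndarray, SubjectReduction]:
    """Reduce one subject's T x V series to its top temporal components.

    T_red is the smallest count whose eigenvalue mass reaches
    ``var_frac`` of the total variance.
    """
    data = b.data if isinstance(b, BoldSeries) else np.asarray(b, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    U, Y, evals, t_red, var_cap, means = _pca_rows(data, var_frac, None)
    return Y, SubjectReduction(
        U=U, eigenvalues=evals, t_red=t_red, var_captured=var_cap, row_means=means
    )


def group_pca(
    subject_Ys: Sequence[np.ndarray],
    var_frac: float | None = 0.99,
    k_fixed: int | None = None,
    subject_ids: Sequence[str] | None = None,
) -> tuple[RepresentativeMatrix, GroupReduction]:
    """Vertically concatenate the reduced subject matrices and run PCA.

    K comes from ``var_frac`` unless ``k_fixed`` overrides it (component
    grids set by cross-validation use the override).
    """
    vs = {y.shape[1] for y in subject_Ys}
    if len(vs) != 1:
        raise ValueError("all subjects must share the same voxel count")
    concat = np.vstack(subject_Ys)
    blocks = []
    start = 0
    for y in subject_Ys:
        blocks.append((start, start + y.shape[0]))
        start += y.shape[0]
    F, X, evals, K, var_cap, means = _pca_rows(concat, var_frac, k_fixed)
    gr = GroupReduction(
        F=F, blocks=blocks, K=K, var_captured=var_cap, eigenvalues=evals, row_means=means
    )
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(len(subject_Ys))]
    return RepresentativeMatrix(X=X, group=gr, subject_ids=ids), gr


def back_reconstruct(
    sr: SubjectReduction,
    gr: GroupReduction,
    subject_index: int,
    A: np.ndarray,
    subject_id: str = "",
) -> SubjectTimecourses:
    """Subject time courses from a group mixing matrix.

    Inverts the group and subject reductions through their pseudo-
    inverses; with orthonormal-row operators the subject-i block of
    pinv(F) is the exact inverse map onto subject i's reduced rows.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != gr.K:
        raise ValueError("A must have K rows")
    if not 0 <= subject_index < len(gr.blocks):
        raise ValueError("invalid subject index")
    start, stop = gr.blocks[subject_index]
    F_pinv_block = np.linalg.pinv(gr.F)[start:stop]  # T_red_i x K
    A_i = np.linalg.pinv(sr.U) @ F_pinv_block @ A
    return SubjectTimecourses(A=A_i, subject_id=subject_id)


def timecourses_by_regression(
    b: BoldSeries | np.ndarray, S: np.ndarray, subject_id: str = ""
) -> SubjectTimecourses:
    """Least-squares projection of a subject's (row-centered) series onto
    fixed spatial maps: A_i = X^i S^+.  Used for subjects that were not
    part of the group decomposition (e.g. holdout scans)."""
    data = b.data if isinstance(b, BoldSeries) else np.asarray(b, dtype=float)
    centered = data - data.mean(axis=1, keepdims=True)
    A_i = centered @ np.linalg.pinv(S)
    return SubjectTimecourses(A=A_i, subject_id=subject_id)


def fmri_feature_vector(tc: SubjectTimecourses) -> np.ndarray:
    """Component-major flattening of the T x C time-course matrix."""
    return tc.A.ravel(order="F")


def save_reductions(
    path: str | Path,
    subject_reductions: dict[str, SubjectReduction],
    gr: GroupReduction,
    X: np.ndarray,
) -> None:
    with h5py.File(path, "w") as f:
        for sid, sr in subject_reductions.items():
            g = f.create_group(f"/U/{sid}")
            g.create_dataset("U", data=sr.U)
            g.create_dataset("eigenvalues", data=sr.eigenvalues)
            g.create_dataset("row_means", data=sr.row_means)
            g.attrs["var_captured"] = sr.var_captured
        f.create_dataset("/F", data=gr.F)
        f.create_dataset("/X", data=X)
        f.create_dataset("/blocks", data=np.asarray(gr.blocks))
        f.create_dataset("/group_eigenvalues", data=gr.eigenvalues)
        f.create_dataset("/group_row_means", data=gr.row_means)
        f.attrs["group_var_captured"] = gr.var_captured


def load_reductions(path: str | Path):
    with h5py.File(path, "r") as f:
        subs = {}
        for sid in f["/U"]:
            g = f[f"/U/{sid}"]
            U = g["U"][()]
            subs[sid] = SubjectReduction(
                U=U,
                eigenvalues=g["eigenvalues"][()],
                t_red=U.shape[0],
                var_captured=float(g.attrs["var_captured"]),
                row_means=g["row_means"][()],
            )
        F = f["/F"][()]
        blocks = [tuple(int(v) for v in b) for b in f["/blocks"][()]]
        gr = GroupReduction(
            F=F,
            blocks=blocks,
            K=F.shape[0],
            var_captured=float(f.attrs["group_var_captured"]),
            eigenvalues=f["/group_eigenvalues"][()],
            row_means=f["/group_row_means"][()],
        )
        X = f["/X"][()]
    return subs, gr, X
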