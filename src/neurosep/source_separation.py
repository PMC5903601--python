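"""Blind source separation backends for the representative matrix.

Four backends map the K x V representative matrix X to spatial maps S
(C x V) and a mixing matrix A (K x C), X ~ A S:

* ``pca`` — the identity backend: S is simply the first C rows of X.
* ``kpca`` — RBF kernel PCA over voxel columns; maps are the top
  eigenvectors of the centered kernel, A a least-squares projection.
* ``ica`` — maximum-likelihood ICA with a Laplacian source prior,
  optimized by natural-gradient ascent on whitened data.
* ``nsd`` — non-stationary spatial source decomposition: each source is
  Laplacian with a location-dependent scale, so local second moments
  R(r) = A D(r) A^T over small regions identify A.  Fitting alternately
  solves nonnegative least squares for the per-region diagonal source
  powers D(r) and descends the summed squared residual in A.

The alignment utilities (Hungarian matching, Amari index) resolve the
permutation/sign/scale indeterminacies inherent to source separation so
estimates can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .fmri_reduction import RepresentativeMatrix

__all__ = [
    "SpatialMapSet",
    "MixingEstimate",
    "LocalCovarianceField",
    "NSDModel",
    "separate_pca",
    "separate_kpca",
    "separate_ica",
    "local_covariances",
    "fit_nsd",
    "extract_nsd_sources",
    "align_components",
    "amari_index",
]

DEFAULT_COMPONENT_GRID = (30, 35, 40, 45, 50, 55)


@dataclass
class SpatialMapSet:
    """C x V spatial components, tagged with their separation backend."""

    S: np.ndarray
    backend: str
    mask_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] < 1:
            raise ValueError("S must be C x V with C >= 1")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("S must be finite")
        if self.backend not in ("pca", "kpca", "ica", "nsd"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def n_components(self) -> int:
        return self.S.shape[0]


@dataclass
class MixingEstimate:
    """Mixing matrix A (K x C) and its pseudo-inverse unmixing W."""

    A: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != self.A.shape[::-1]:
            raise ValueError("W must be the C x K counterpart of A")
        if np.linalg.norm(self.A @ self.W @ self.A - self.A) > 1e-6 * max(
            1.0, np.linalg.norm(self.A)
        ):
            raise ValueError("W is not a pseudo-inverse of A")


@dataclass
class LocalCovarianceField:
    """Per-region second-moment matrices of the representative matrix."""

    regions: list[tuple[tuple[int, int, int], np.ndarray]]  # (corner, voxel column idx)
    R_hat: list[np.ndarray]  # per-region K x K symmetric PSD

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.R_hat):
            raise ValueError("one matrix per region required")
        for R in self.R_hat:
            if np.linalg.norm(R - R.T) > 1e-8 * max(1.0, np.linalg.norm(R)):
                raise ValueError("R_hat must be symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.R_hat)

    @property
    def K(self) -> int:
        return self.R_hat[0].shape[0]


@dataclass
class NSDModel:
    """Fitted non-stationary decomposition."""

    A: np.ndarray  # K x C, unit-norm columns
    D: np.ndarray  # n_regions x C nonnegative source powers
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        if np.any(self.D < 0):
            raise ValueError("source powers must be nonnegative")


def separate_pca(X: RepresentativeMatrix | np.ndarray, C: int) -> tuple[SpatialMapSet, MixingEstimate]:
    """Identity backend: keep the first C rows of X as spatial maps."""
    Xm = X.X if isinstance(X, RepresentativeMatrix) else np.asarray(X, dtype=float)
    K = Xm.shape[0]
    if C > K:
        raise ValueError("C cannot exceed K")
    S = Xm[:C].copy()
    A = np.eye(K)[:, :C]
    return SpatialMapSet(S=S, backend="pca"), MixingEstimate(A=A, W=A.T)


def separate_kpca(
    X: RepresentativeMatrix | np.ndarray,
    sigma: float,
    C: int,
    max_voxels: int = 20000,
) -> tuple[SpatialMapSet, MixingEstimate]:
    """RBF kernel PCA over voxel columns.

    The V x V kernel exp(-||x_i - x_j||^2 / (2 sigma^2)) is centered and
    eigendecomposed; the top-C eigenvectors (unit norm, one weight per
    voxel) are the spatial maps and A is the least-squares projection of
    X onto them.  Guarded by ``max_voxels`` since the kernel is dense.
    """
    Xm = X.X if isinstance(X, RepresentativeMatrix) else np.asarray(X, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    K, V = Xm.shape
    if V > max_voxels:
        raise ValueError(f"V={V} exceeds the kernel feasibility limit {max_voxels}")
    if C > min(K, V):
        raise ValueError("C too large")
    sq = np.sum(Xm**2, axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xm.T @ Xm)
    np.maximum(d2, 0.0, out=d2)
    Kmat = np.exp(-d2 / (2.0 * sigma**2))
    # double centering in feature space
    row = Kmat.mean(axis=0)
    Kc = Kmat - row[None, :] - row[:, None] + row.mean()
    evals, evecs = np.linalg.eigh(Kc)
    scale = max(1.0, float(np.abs(evals).max()))
    if evals.min() < -1e-8 * scale:
        raise ValueError("centered kernel is not PSD within tolerance")
    order = np.argsort(evals)[::-1][:C]
    S = evecs[:, order].T  # C x V, orthonormal rows
    A = Xm @ S.T  # least squares since rows of S are orthonormal
    return SpatialMapSet(S=S, backend="kpca"), MixingEstimate(A=A, W=np.linalg.pinv(A))


def _order_and_sign(S: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic component convention: descending row variance of S,
    sign such that each row's largest-magnitude entry is positive."""
    order = np.argsort(-S.var(axis=1), kind="stable")
    S = S[order]
    A = A[:, order]
    for i in range(S.shape[0]):
        j = int(np.argmax(np.abs(S[i])))
        if S[i, j] < 0:
            S[i] *= -1.0
            A[:, i] *= -1.0
    return S, A


def separate_ica(
    X: RepresentativeMatrix | np.ndarray,
    C: int | None = None,
    seed: int = 0,
    max_epochs: int = 1000,
    step0: float = 0.1,
    tol: float = 1e-9,
) -> tuple[SpatialMapSet, MixingEstimate]:
    """Maximum-likelihood ICA with a unit-scale Laplacian source prior.

    Rows of X are whitened (PCA to C dimensions), then the square
    unmixing W is fit by natural-gradient ascent on

        L(W) = sum_h sum_j log p(w_h^T x_j) + V log|det W|

    with p the Laplacian density; the natural-gradient update is
    W <- W + mu (I - sign(s) s^T / V) W.  Steps that decrease the
    likelihood are rejected and the step size halved (annealing);
    the source scale indeterminacy is absorbed into A.
    """
    Xm = X.X if isinstance(X, RepresentativeMatrix) else np.asarray(X, dtype=float)
    K, V = Xm.shape
    if C is None:
        C = K
    if C > K:
        raise ValueError("C cannot exceed K")
    centered = Xm - Xm.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / V
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:C]
    ev = evals[order]
    if np.any(ev <= 1e-10 * max(evals.max(), 1e-300)):
        raise ValueError("data rank below the requested component count")
    wh = (evecs[:, order] / np.sqrt(ev)).T  # C x K whitening
    Z = wh @ centered

    rng = np.random.default_rng(seed)
    W = np.eye(C) + 1e-3 * rng.standard_normal((C, C))

    def loglik(Wc: np.ndarray) -> float:
        s = Wc @ Z
        sign, logdet = np.linalg.slogdet(Wc)
        if sign <= 0 and abs(logdet) == np.inf:
            return -np.inf
        return float(-np.abs(s).sum() + V * logdet)

    ll = loglik(W)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite initial likelihood")
    mu = step0
    converged = False
    for _ in range(max_epochs):
        s = W @ Z
        G = np.eye(C) - (np.sign(s) @ s.T) / V
        W_new = W + mu * (G @ W)
        ll_new = loglik(W_new)
        if np.isfinite(ll_new) and ll_new >= ll:
            if ll_new - ll < tol * max(1.0, abs(ll)) and np.linalg.norm(G) < 1e-5 * C:
                W, ll = W_new, ll_new
                converged = True
                break
            W, ll = W_new, ll_new
            mu = min(mu * 1.05, step0)
        else:
            mu *= 0.5
            if mu < 1e-14:
                break

    S = W @ Z
    W_total = W @ wh  # C x K on the centered X scale
    A = np.linalg.pinv(W_total)
    S, A = _order_and_sign(S, A)
    return (
        SpatialMapSet(S=S, backend="ica"),
        MixingEstimate(A=A, W=np.linalg.pinv(A)),
    )


def local_covariances(
    X: RepresentativeMatrix | np.ndarray,
    mask: np.ndarray,
    box_edge: int = 4,
    center: bool = False,
) -> LocalCovarianceField:
    """Second-moment matrices over a disjoint cubic tiling of the mask.

    The mask's true voxels (C order) index the columns of X.  Each
    box_edge^3 box (trailing partial boxes kept) with at least one mask
    voxel contributes R(r) = mean over its voxels of x x^T.
    """
    Xm = X.X if isinstance(X, RepresentativeMatrix) else np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if box_edge < 1:
        raise ValueError("box_edge must be >= 1")
    if int(mask.sum()) != Xm.shape[1]:
        raise ValueError("mask voxel count must match the columns of X")
    col_of = -np.ones(mask.shape, dtype=int)
    col_of[mask] = np.arange(int(mask.sum()))
    nx, ny, nz = mask.shape
    regions: list[tuple[tuple[int, int, int], np.ndarray]] = []
    R_hat: list[np.ndarray] = []
    for x0 in range(0, nx, box_edge):
        for y0 in range(0, ny, box_edge):
            for z0 in range(0, nz, box_edge):
                sub = col_of[x0 : x0 + box_edge, y0 : y0 + box_edge, z0 : z0 + box_edge]
                cols = sub[sub >= 0]
                if cols.size == 0:
                    continue
                x = Xm[:, cols]
                if center:
                    x = x - x.mean(axis=1, keepdims=True)
                R = x @ x.T / cols.size
                regions.append(((x0, y0, z0), cols))
                R_hat.append(0.5 * (R + R.T))
    if not R_hat:
        raise ValueError("mask produced no regions")
    return LocalCovarianceField(regions=regions, R_hat=R_hat)


def _nsd_objective(R_hat: list[np.ndarray], A: np.ndarray, D: np.ndarray) -> float:
    return float(
        sum(
            np.sum((R - (A * D[k]) @ A.T) ** 2)
            for k, R in enumerate(R_hat)
        )
    )


def _nsd_d_step(R_hat: list[np.ndarray], A: np.ndarray) -> np.ndarray:
    """Optimal nonnegative diagonal source powers for fixed A."""
    K, C = A.shape
    M = np.empty((K * K, C))
    for c in range(C):
        M[:, c] = np.outer(A[:, c], A[:, c]).ravel()
    D = np.empty((len(R_hat), C))
    for k, R in enumerate(R_hat):
        D[k], _ = nnls(M, R.ravel())
    return D


def _nsd_a_step(
    R_hat: list[np.ndarray],
    A: np.ndarray,
    D: np.ndarray,
    obj: float,
    n_steps: int,
    step: float,
) -> tuple[np.ndarray, float, float]:
    """Backtracking gradient descent in A for fixed D."""
    for _ in range(n_steps):
        grad = np.zeros_like(A)
        for k, R in enumerate(R_hat):
            E = R - (A * D[k]) @ A.T
            grad -= 4.0 * E @ (A * D[k])
        gnorm2 = float(np.sum(grad**2))
        if gnorm2 == 0.0:
            break
        improved = False
        while step > 1e-18:
            A_new = A - step * grad
            obj_new = _nsd_objective(R_hat, A_new, D)
            if obj_new <= obj - 1e-4 * step * gnorm2:
                A, obj = A_new, obj_new
                step *= 2.0
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return A, obj, step


def fit_nsd(
    field: LocalCovarianceField,
    C: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_sweeps: int = 500,
    inner_steps: int = 25,
) -> NSDModel:
    """Alternating minimization of sum_k ||R_hat(r_k) - A D(r_k) A^T||^2.

    Each sweep solves the per-region nonnegative least-squares problem
    for the diagonal powers exactly, then runs backtracking gradient
    descent in A; columns of A are renormalized to unit norm after every
    sweep with the scale absorbed into the powers (the objective is
    invariant under this).  A is initialized from the top-C eigenvectors
    of the mean local second moment.
    """
    R_hat = field.R_hat
    K = field.K
    if C is None:
        C = K
    if C > K:
        raise ValueError("C cannot exceed K")
    if len(R_hat) < 2:
        raise ValueError("need at least 2 regions")
    R_mean = sum(R_hat) / len(R_hat)
    if np.allclose(R_mean, 0.0):
        raise ValueError("degenerate all-zero covariance field")
    evals, evecs = np.linalg.eigh(R_mean)
    A = evecs[:, np.argsort(evals)[::-1][:C]].copy()
    rng = np.random.default_rng(seed)
    A += 1e-6 * rng.standard_normal(A.shape)  # break exact symmetry ties
    A /= np.linalg.norm(A, axis=0, keepdims=True)

    D = _nsd_d_step(R_hat, A)
    obj = _nsd_objective(R_hat, A, D)
    trace = [obj]
    step = 1.0 / max(1.0, float(np.linalg.norm(R_mean)))
    converged = False
    for _ in range(max_sweeps):
        A, obj, step = _nsd_a_step(R_hat, A, D, obj, inner_steps, step)
        # renormalize columns; D absorbs the squared norms
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        A = A / norms
        D = D * norms[None, :] ** 2
        D = _nsd_d_step(R_hat, A)
        obj_new = _nsd_objective(R_hat, A, D)
        if obj_new > obj + 1e-12 * max(1.0, obj):
            raise RuntimeError("NSD objective increased across a sweep")
        rel = (trace[-1] - obj_new) / max(trace[-1], 1e-300)
        trace.append(obj_new)
        obj = obj_new
        if rel < tol:
            converged = True
            break
    return NSDModel(A=A, D=D, objective_trace=trace, converged=converged)


def extract_nsd_sources(
    X: RepresentativeMatrix | np.ndarray,
    model: NSDModel,
    force: bool = False,
    mask_shape: tuple[int, int, int] | None = None,
) -> SpatialMapSet:
    """Columnwise least-squares source estimates S = A^+ X."""
    if not model.converged and not force:
        raise RuntimeError("model did not converge; pass force=True to extract anyway")
    Xm = X.X if isinstance(X, RepresentativeMatrix) else np.asarray(X, dtype=float)
    S = np.linalg.pinv(model.A) @ Xm
    return SpatialMapSet(S=S, backend="nsd", mask_shape=mask_shape)


def amari_index(G: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of a gain matrix.

    0 iff G is a scaled permutation (perfect separation); normalized to
    lie in [0, 1].
    """
    g = np.abs(np.asarray(G, dtype=float))
    C = g.shape[0]
    if g.shape != (C, C) or C < 2:
        raise ValueError("G must be square with C >= 2")
    rows = (g / g.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (g / g.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * C * (C - 1)))


def align_components(
    S_est: np.ndarray, S_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Match estimated to true components.

    Solves the assignment problem maximizing the summed |correlation|,
    and returns (permutation, signs, per-component correlations, Amari
    index of the induced gain matrix G = S_est S_true^+ — how each
    estimated map decomposes over the true maps; G is a scaled
    permutation iff separation is perfect).  ``permutation[i]`` is the
    index of the estimated component matched to true component i.
    """
    S_est = np.asarray(S_est, dtype=float)
    S_true = np.asarray(S_true, dtype=float)
    if S_est.shape != S_true.shape:
        raise ValueError("shape mismatch")
    if np.any(S_est.std(axis=1) == 0) or np.any(S_true.std(axis=1) == 0):
        raise ValueError("zero-variance component")
    E = (S_est - S_est.mean(axis=1, keepdims=True)) / S_est.std(axis=1, keepdims=True)
    T = (S_true - S_true.mean(axis=1, keepdims=True)) / S_true.std(axis=1, keepdims=True)
    corr = (T @ E.T) / S_est.shape[1]  # true x est
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = cols[np.argsort(rows)]
    matched = corr[np.arange(len(perm)), perm]
    signs = np.where(matched >= 0, 1.0, -1.0)
    gain = S_est @ np.linalg.pinv(S_true)
    return perm, signs, np.abs(matched), amari_index(gain)


def save_separation(
    path: str | Path,
    maps: SpatialMapSet,
    mixing: MixingEstimate,
    model: NSDModel | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("/S", data=maps.S)
        f.attrs["backend"] = maps.backend
        f.create_dataset("/A", data=mixing.A)
        if model is not None:
            f.create_dataset("/D", data=model.D)
            f.create_dataset("/trace", data=np.asarray(model.objective_trace))


def load_separation(path: str | Path) -> tuple[SpatialMapSet, MixingEstimate]:
    with h5py.File(path, "r") as f:
        S = f["/S"][()]
        backend = str(f.attrs["backend"])
        A = f["/A"][()]
    return SpatialMapSet(S=S, backend=backend), MixingEstimate(A=A, W=np.linalg.pinv(A))
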