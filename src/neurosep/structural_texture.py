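"""Texture feature learning from structural volumes.

The pipeline is: sample every 5x5x5 patch of the (z-normalized) volume,
learn k texture filters with a single-layer sparse autoencoder, convolve
each filter over the whole volume with a sigmoid non-linearity, then
max-pool over disjoint 5x5x5 blocks and concatenate the pooled maps into
one feature vector per subject.

The autoencoder minimizes

    J(theta, b) = 1/(2|D|) sum_x ||x - xhat||^2
                  + beta * sum_j KL(rho || rhohat_j)
                  + lam * ||theta||^2

with h = sigmoid(theta1 x + b1), xhat = sigmoid(theta2 h + b2), and
rhohat_j the mean activation of hidden unit j over the data.  The KL
sparsity penalty drives hidden units towards rarely-active, distinct
texture detectors.  Optimization is quasi-Newton (L-BFGS) on the exact
analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
from scipy.optimize import minimize
from scipy.signal import correlate

from .cohort_io import Volume3D

__all__ = [
    "PatchMatrix",
    "AutoencoderParams",
    "FilterBank",
    "TextureFeatures",
    "sigmoid",
    "extract_patches",
    "ae_objective",
    "train_autoencoder",
    "select_autoencoder_hyperparameters",
    "convolve_sigmoid_3d",
    "max_pool_3d",
    "pooled_grid_dims",
    "structural_feature_vector",
    "save_filter_bank",
    "load_filter_bank",
]

_EPS = 1e-8  # activation clamp keeping the KL term finite


def sigmoid(t: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-t))."""
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class PatchMatrix:
    """m x n matrix of flattened cubic patches (n = edge**3)."""

    patches: np.ndarray
    edge: int = 5
    source_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.ndim != 2 or self.patches.shape[1] != self.edge**3:
            raise ValueError("patches must be m x edge**3")
        if not np.all(np.isfinite(self.patches)):
            raise ValueError("patches must be finite")

    def __len__(self) -> int:
        return self.patches.shape[0]


@dataclass
class AutoencoderParams:
    """Weights/biases plus the sparsity and decay hyperparameters."""

    theta1: np.ndarray  # k x n encoding weights
    b1: np.ndarray  # k encoding biases
    theta2: np.ndarray  # n x k decoding weights
    b2: np.ndarray  # n decoding biases
    rho: float = 0.05
    beta: float = 1.0
    lam: float = 1e-4

    def __post_init__(self) -> None:
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        k, n = self.theta1.shape
        if self.theta2.shape != (n, k) or self.b1.shape != (k,) or self.b2.shape != (n,):
            raise ValueError("inconsistent parameter shapes")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")

    @property
    def k(self) -> int:
        return self.theta1.shape[0]

    @property
    def n(self) -> int:
        return self.theta1.shape[1]

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.theta1.ravel(), self.b1, self.theta2.ravel(), self.b2]
        )

    def with_flat(self, flat: np.ndarray) -> "AutoencoderParams":
        k, n = self.k, self.n
        i0 = k * n
        i1 = i0 + k
        i2 = i1 + n * k
        return AutoencoderParams(
            theta1=flat[:i0].reshape(k, n),
            b1=flat[i0:i1],
            theta2=flat[i1:i2].reshape(n, k),
            b2=flat[i2:],
            rho=self.rho,
            beta=self.beta,
            lam=self.lam,
        )


@dataclass
class FilterBank:
    """k learned cubic filters (rows of theta1 reshaped) with biases."""

    filters: np.ndarray  # k x e x e x e
    biases: np.ndarray  # k

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.filters.ndim != 4 or self.filters.shape[0] != self.biases.shape[0]:
            raise ValueError("need one bias per filter")

    @property
    def k(self) -> int:
        return self.filters.shape[0]

    @property
    def edge(self) -> int:
        return self.filters.shape[1]

    @classmethod
    def from_params(cls, params: AutoencoderParams, edge: int) -> "FilterBank":
        return cls(
            filters=params.theta1.reshape(params.k, edge, edge, edge).copy(),
            biases=params.b1.copy(),
        )


@dataclass
class TextureFeatures:
    vector: np.ndarray
    pooled_grid_dims: tuple[int, int, int]
    k: int

    def __post_init__(self) -> None:
        gx, gy, gz = self.pooled_grid_dims
        if self.vector.shape != (self.k * gx * gy * gz,):
            raise ValueError("feature length must be k * gx * gy * gz")


def extract_patches(
    v: Volume3D,
    edge: int = 5,
    stride: int = 1,
    max_patches: int | None = None,
    seed: int | None = None,
) -> PatchMatrix:
    """All cubic patches of the volume at the given stride, flattened.

    With stride 1 there is one patch per corner position, i.e.
    prod(dim - edge + 1) patches, roughly one per voxel.  When
    ``max_patches`` is given, a seeded uniform subsample of rows is kept.
    """
    arr = v.intensities
    if min(arr.shape) < edge:
        raise ValueError(f"volume {arr.shape} smaller than patch edge {edge}")
    win = np.lib.stride_tricks.sliding_window_view(arr, (edge, edge, edge))
    win = win[::stride, ::stride, ::stride]
    gx, gy, gz = win.shape[:3]
    patches = win.reshape(gx * gy * gz, edge**3)
    corners = np.stack(
        np.meshgrid(
            np.arange(gx) * stride,
            np.arange(gy) * stride,
            np.arange(gz) * stride,
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    if max_patches is not None and len(patches) > max_patches:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(patches), size=max_patches, replace=False)
        keep.sort()
        patches = patches[keep]
        corners = corners[keep]
    return PatchMatrix(patches=np.ascontiguousarray(patches), edge=edge, source_positions=corners)


def _kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    rho_hat = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    return rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))


def ae_objective(params: AutoencoderParams, D: PatchMatrix | np.ndarray) -> tuple[float, np.ndarray]:
    """Sparse-autoencoder objective and its exact gradient.

    Returns ``(J, grad)`` with ``grad`` flattened in the order
    theta1, b1, theta2, b2 (matching :meth:`AutoencoderParams.pack`).
    """
    X = D.patches if isinstance(D, PatchMatrix) else np.asarray(D, dtype=float)
    m = X.shape[0]
    if m < 1:
        raise ValueError("need at least one data row")

    a2 = sigmoid(X @ params.theta1.T + params.b1)  # m x k hidden activations
    a3 = sigmoid(a2 @ params.theta2.T + params.b2)  # m x n reconstruction

    diff = a3 - X
    recon = float(np.sum(diff**2)) / (2.0 * m)

    rho_hat = a2.mean(axis=0)
    rho_hat_c = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    sparsity = float(np.sum(_kl_bernoulli(params.rho, rho_hat)))
    decay = float(np.sum(params.theta1**2) + np.sum(params.theta2**2))
    J = recon + params.beta * sparsity + params.lam * decay

    # Backprop.  The sparsity penalty reaches theta1 through rho_hat,
    # which averages over the batch: its per-sample contribution is the
    # KL derivative divided by m.
    d3 = (diff / m) * a3 * (1.0 - a3)  # m x n
    kl_grad = -params.rho / rho_hat_c + (1.0 - params.rho) / (1.0 - rho_hat_c)  # k
    d2 = (d3 @ params.theta2 + params.beta * kl_grad / m) * a2 * (1.0 - a2)  # m x k

    g_theta2 = d3.T @ a2 + 2.0 * params.lam * params.theta2
    g_b2 = d3.sum(axis=0)
    g_theta1 = d2.T @ X + 2.0 * params.lam * params.theta1
    g_b1 = d2.sum(axis=0)

    grad = np.concatenate([g_theta1.ravel(), g_b1, g_theta2.ravel(), g_b2])
    return J, grad


def init_autoencoder(
    n: int,
    k: int,
    rho: float = 0.05,
    beta: float = 1.0,
    lam: float = 1e-4,
    seed: int | None = 0,
) -> AutoencoderParams:
    """Symmetric uniform init in +-sqrt(6 / (n + k)); biases at zero."""
    rng = np.random.default_rng(seed)
    r = np.sqrt(6.0 / (n + k))
    return AutoencoderParams(
        theta1=rng.uniform(-r, r, size=(k, n)),
        b1=np.zeros(k),
        theta2=rng.uniform(-r, r, size=(n, k)),
        b2=np.zeros(n),
        rho=rho,
        beta=beta,
        lam=lam,
    )


def train_autoencoder(
    D: PatchMatrix,
    k: int = 3,
    rho: float = 0.05,
    beta: float = 1.0,
    lam: float = 1e-4,
    seed: int | None = 0,
    max_iter: int = 400,
    gtol: float = 1e-5,
) -> tuple[AutoencoderParams, FilterBank]:
    """L-BFGS minimization of :func:`ae_objective` from a seeded init.

    Stops at gradient-infinity-norm below ``gtol`` or ``max_iter``
    iterations; the filter bank is read off the encoding weights/biases.
    """
    if len(D) < k:
        raise ValueError("need at least k patches")
    n = D.patches.shape[1]
    p0 = init_autoencoder(n, k, rho=rho, beta=beta, lam=lam, seed=seed)

    def fun(flat: np.ndarray) -> tuple[float, np.ndarray]:
        J, g = ae_objective(p0.with_flat(flat), D)
        if not np.isfinite(J):
            raise FloatingPointError("non-finite autoencoder objective")
        return J, g

    res = minimize(
        fun,
        p0.pack(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    params = p0.with_flat(res.x)
    return params, FilterBank.from_params(params, edge=D.edge)


def select_autoencoder_hyperparameters(
    D: PatchMatrix,
    k: int = 3,
    beta_grid: Iterable[float] = (0.1, 1.0, 3.0),
    lam_grid: Iterable[float] = (1e-4, 1e-3),
    rho_grid: Iterable[float] = (0.01, 0.05),
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 200,
) -> dict[str, float]:
    """Pick (beta, lam, rho) by internal k-fold CV on held-out
    reconstruction error; ties go to the first grid point."""
    rng = np.random.default_rng(seed)
    m = len(D)
    order = rng.permutation(m)
    folds = np.array_split(order, n_folds)
    best: tuple[float, dict[str, float]] | None = None
    for rho in rho_grid:
        for beta in beta_grid:
            for lam in lam_grid:
                errs = []
                for i, test_idx in enumerate(folds):
                    train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
                    sub = PatchMatrix(D.patches[train_idx], edge=D.edge)
                    params, _ = train_autoencoder(
                        sub, k=k, rho=rho, beta=beta, lam=lam, seed=seed, max_iter=max_iter
                    )
                    Xt = D.patches[test_idx]
                    h = sigmoid(Xt @ params.theta1.T + params.b1)
                    xhat = sigmoid(h @ params.theta2.T + params.b2)
                    errs.append(float(np.mean((Xt - xhat) ** 2)))
                score = float(np.mean(errs))
                if best is None or score < best[0]:
                    best = (score, {"beta": beta, "lam": lam, "rho": rho})
    assert best is not None
    return best[1]


def convolve_sigmoid_3d(v: Volume3D | np.ndarray, f: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Valid (no padding) correlation of a cubic filter with a volume,
    plus bias, through the sigmoid.  Output dims = input - filter + 1."""
    arr = v.intensities if isinstance(v, Volume3D) else np.asarray(v, dtype=float)
    f = np.asarray(f, dtype=float)
    if any(a < b for a, b in zip(arr.shape, f.shape)):
        raise ValueError("volume smaller than filter")
    return sigmoid(correlate(arr, f, mode="valid") + bias)


def pooled_grid_dims(
    dims: tuple[int, int, int], pool_edge: int, mode: str = "ceil"
) -> tuple[int, int, int]:
    """Pooled-grid dimensions: ``ceil`` keeps trailing partial boxes as
    their own cells; ``round`` reproduces printed grids that round
    dim/pool to the nearest integer (the trailing box absorbs or loses
    the remainder)."""
    if pool_edge < 1:
        raise ValueError("pool_edge must be >= 1")
    if mode == "ceil":
        return tuple(-(-d // pool_edge) for d in dims)  # type: ignore[return-value]
    if mode == "round":
        return tuple(max(1, round(d / pool_edge)) for d in dims)  # type: ignore[return-value]
    raise ValueError(f"unknown pooling mode {mode!r}")


def _axis_boundaries(dim: int, pool_edge: int, g: int) -> list[tuple[int, int]]:
    # g cells; all but the last have width pool_edge, the last runs to dim.
    return [(i * pool_edge, dim if i == g - 1 else (i + 1) * pool_edge) for i in range(g)]


def max_pool_3d(arr: np.ndarray, pool_edge: int = 5, mode: str = "ceil") -> np.ndarray:
    """Max over disjoint, exhaustive cubic sub-regions.

    ``mode='ceil'`` tiles with ceil(dim/pool) cells per axis (partial
    trailing boxes included); ``mode='round'`` uses round(dim/pool)
    cells, with the trailing cell cropped or extended to the boundary.
    """
    arr = np.asarray(arr, dtype=float)
    dims = arr.shape
    grid = pooled_grid_dims(dims, pool_edge, mode=mode)
    bx = _axis_boundaries(dims[0], pool_edge, grid[0])
    by = _axis_boundaries(dims[1], pool_edge, grid[1])
    bz = _axis_boundaries(dims[2], pool_edge, grid[2])
    out = np.empty(grid, dtype=float)
    for i, (x0, x1) in enumerate(bx):
        for j, (y0, y1) in enumerate(by):
            for k, (z0, z1) in enumerate(bz):
                out[i, j, k] = arr[x0:x1, y0:y1, z0:z1].max()
    return out


def structural_feature_vector(
    v: Volume3D,
    bank: FilterBank,
    pool_edge: int = 5,
    mode: str = "ceil",
) -> TextureFeatures:
    """Convolve every filter, pool, and concatenate filter-major."""
    if bank.k < 1:
        raise ValueError("empty filter bank")
    pooled = [
        max_pool_3d(
            convolve_sigmoid_3d(v, bank.filters[i], bank.biases[i]),
            pool_edge=pool_edge,
            mode=mode,
        )
        for i in range(bank.k)
    ]
    grid = pooled[0].shape
    vec = np.concatenate([p.ravel() for p in pooled])
    return TextureFeatures(vector=vec, pooled_grid_dims=grid, k=bank.k)


def save_filter_bank(bank: FilterBank, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("/filters", data=bank.filters)
        f.create_dataset("/biases", data=bank.biases)


def load_filter_bank(path: str | Path) -> FilterBank:
    with h5py.File(path, "r") as f:
        return FilterBank(filters=f["/filters"][()], biases=f["/biases"][()])


def save_texture_features(
    features: np.ndarray, pooled_dims: tuple[int, int, int], path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("/features", data=np.asarray(features))
        f.create_dataset("/pooled_dims", data=np.asarray(pooled_dims))


def load_texture_features(path: str | Path) -> tuple[np.ndarray, tuple[int, int, int]]:
    with h5py.File(path, "r") as f:
        feats = f["/features"][()]
        dims = tuple(int(d) for d in f["/pooled_dims"][()])
    return feats, dims  # type: ignore[return-value]
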