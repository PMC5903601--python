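"""End-to-end orchestration of the three learners.

Mode ``S`` classifies on structural texture features, mode ``F`` on
source-separation time-course features, mode ``SF`` on their
concatenation.  Everything that is *learned* — texture filters, group
PCA operators, spatial maps, feature scalers, SVM hyperparameters — is
fit on the training split only; holdout subjects pass through the fixed
transforms (filters are applied as-is, time courses come from
least-squares projection onto the fixed spatial maps) and are touched
exactly once, for the final evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import classify_eval as ce
from . import cohort_io as cio
from . import fmri_reduction as fr
from . import source_separation as ss
from . import structural_texture as st

logger = logging.getLogger("neurosep")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "structural_feature_matrix",
    "fmri_feature_matrix",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    cohort_path: str = "cohort.tsv"
    mode: str = "SF"  # S | F | SF
    backend: str = "nsd"  # pca | kpca | ica | nsd
    n_components: int | None = None  # None: K from group var_frac
    component_grid: tuple[int, ...] | None = None  # CV over C when given
    var_frac: float = 0.99
    fwhm_mm: float = 8.0
    k_filters: int = 3
    patch_edge: int = 5
    pool_edge: int = 5
    pool_mode: str = "ceil"
    max_patches: int = 100_000
    ae_beta: float = 1.0
    ae_lam: float = 1e-4
    ae_rho: float = 0.05
    kpca_sigma: float = 1.0
    box_edge: int = 4
    standardize_fmri: bool = True
    standardize_mri: bool = False
    cv_folds: int = 5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("S", "F", "SF"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.backend not in ("pca", "kpca", "ica", "nsd"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "component_grid" in raw and raw["component_grid"] is not None:
            raw["component_grid"] = tuple(raw["component_grid"])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: ce.EvalReport
    cv_accuracy: float | None
    gamma: float | None
    n_components: int | None
    predictions: "np.ndarray"
    truth: "np.ndarray"
    subject_ids: list[str]
    manifest: dict


def structural_feature_matrix(
    volumes: Sequence[cio.Volume3D],
    train_idx: np.ndarray,
    k: int = 3,
    patch_edge: int = 5,
    pool_edge: int = 5,
    pool_mode: str = "ceil",
    max_patches: int = 100_000,
    beta: float = 1.0,
    lam: float = 1e-4,
    rho: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, st.FilterBank]:
    """Learn the filter bank on training volumes only; featurize all.

    Patches are pooled across training subjects up to ``max_patches``
    rows (seeded uniform subsample), the autoencoder is trained once,
    and the fixed bank is convolved over every subject's volume.
    """
    per_subject = max(1, max_patches // max(1, len(train_idx)))
    blocks = []
    for j, i in enumerate(train_idx):
        pm = st.extract_patches(
            volumes[i], edge=patch_edge, max_patches=per_subject, seed=seed + 17 * j
        )
        blocks.append(pm.patches)
    D = st.PatchMatrix(np.vstack(blocks), edge=patch_edge)
    _, bank = st.train_autoencoder(D, k=k, rho=rho, beta=beta, lam=lam, seed=seed)
    feats = np.stack(
        [
            st.structural_feature_vector(v, bank, pool_edge=pool_edge, mode=pool_mode).vector
            for v in volumes
        ]
    )
    return feats, bank


def _separate(X: np.ndarray, backend: str, C: int, cfg: PipelineConfig):
    if backend == "pca":
        return ss.separate_pca(X, C)
    if backend == "kpca":
        return ss.separate_kpca(X, sigma=cfg.kpca_sigma, C=C)
    if backend == "ica":
        return ss.separate_ica(X, C=C, seed=cfg.seed)
    raise ValueError(f"backend {backend!r} is not handled here")  # nsd needs mask geometry


def fmri_feature_matrix(
    series: Sequence[cio.BoldSeries],
    train_idx: np.ndarray,
    cfg: PipelineConfig,
    n_components: int | None = None,
) -> tuple[np.ndarray, ss.SpatialMapSet, int]:
    """Time-course features for every subject from train-only group maps.

    Subject-level PCA runs per subject; group PCA and source separation
    see training subjects only.  Training subjects get time courses by
    inverting the two reductions; all other subjects are projected onto
    the fixed spatial maps by least squares.
    """
    train_idx = np.asarray(train_idx)
    reductions: dict[int, fr.SubjectReduction] = {}
    Ys = {}
    for i, b in enumerate(series):
        Y, sr = fr.subject_pca(b, var_frac=cfg.var_frac)
        reductions[i] = sr
        Ys[i] = Y
    rep, gr = fr.group_pca(
        [Ys[i] for i in train_idx],
        var_frac=cfg.var_frac,
        subject_ids=[series[i].subject_id for i in train_idx],
    )
    C = n_components if n_components is not None else rep.K
    if C > rep.K:
        logger.warning("requested C=%d exceeds K=%d; raising K", C, rep.K)
        rep, gr = fr.group_pca(
            [Ys[i] for i in train_idx],
            var_frac=None,
            k_fixed=C,
            subject_ids=[series[i].subject_id for i in train_idx],
        )
    if cfg.backend == "nsd":
        field_ = ss.local_covariances(rep.X, series[0].mask, box_edge=cfg.box_edge)
        model = ss.fit_nsd(field_, C=C, seed=cfg.seed)
        maps = ss.extract_nsd_sources(rep.X, model, force=True)
        mixing = ss.MixingEstimate(A=model.A, W=np.linalg.pinv(model.A))
    else:
        maps, mixing = _separate(rep.X, cfg.backend, C, cfg)
    tcs: list[fr.SubjectTimecourses] = []
    for i, b in enumerate(series):
        pos = np.flatnonzero(train_idx == i)
        if pos.size:
            tcs.append(
                fr.back_reconstruct(
                    reductions[i], gr, int(pos[0]), mixing.A, subject_id=b.subject_id
                )
            )
        else:
            tcs.append(fr.timecourses_by_regression(b, maps.S, subject_id=b.subject_id))
    feats = np.stack([fr.fmri_feature_vector(tc) for tc in tcs])
    return feats, maps, C


def _load_inputs(cfg: PipelineConfig):
    cohort = cio.load_cohort(cfg.cohort_path)
    base = Path(cfg.cohort_path).parent
    volumes = []
    series = []
    t_common = None
    if cfg.mode in ("S", "SF"):
        for _, row in cohort.frame.iterrows():
            v = cio.load_volume(base / row["structural_path"])
            volumes.append(cio.Volume3D(cio.z_normalize(v.intensities), v.voxel_size, v.affine))
    if cfg.mode in ("F", "SF"):
        all_frames = [
            cio.load_series(base / row["functional_path"])
            for _, row in cohort.frame.iterrows()
        ]
        t_common = min(len(fs) for fs in all_frames)
        mask = np.ones(all_frames[0][0].shape, dtype=bool)
        for (_, row), frames in zip(cohort.frame.iterrows(), all_frames):
            if cfg.fwhm_mm > 0:
                frames = [cio.smooth_volume(f, cfg.fwhm_mm) for f in frames]
            frames = [
                cio.Volume3D(cio.z_normalize(f.intensities), f.voxel_size, f.affine)
                for f in frames
            ]
            series.append(
                cio.vectorize_series(
                    frames,
                    mask,
                    t_common,
                    subject_id=row["subject_id"],
                    site=row["site"],
                    label=row["label"],
                )
            )
    return cohort, volumes, series


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute one mode end to end and evaluate once on the holdout split."""
    cohort, volumes, series = _load_inputs(cfg)
    labels = cohort.labels
    splits = cohort.frame["split"].to_numpy()
    train_idx = np.flatnonzero(splits == "train")
    hold_idx = np.flatnonzero(splits == "holdout")
    if train_idx.size == 0 or hold_idx.size == 0:
        raise ValueError("cohort must contain both train and holdout subjects")

    blocks = []
    standardize = False
    n_comp_used = None
    if cfg.mode in ("S", "SF"):
        mri_feats, _ = structural_feature_matrix(
            volumes,
            train_idx,
            k=cfg.k_filters,
            patch_edge=cfg.patch_edge,
            pool_edge=cfg.pool_edge,
            pool_mode=cfg.pool_mode,
            max_patches=cfg.max_patches,
            beta=cfg.ae_beta,
            lam=cfg.ae_lam,
            rho=cfg.ae_rho,
            seed=cfg.seed,
        )
        blocks.append(mri_feats)
        standardize = standardize or cfg.standardize_mri
    if cfg.mode in ("F", "SF"):
        C = cfg.n_components
        if cfg.component_grid:
            C = _select_components(series, train_idx, labels, cfg)
        fmri_feats, _, n_comp_used = fmri_feature_matrix(series, train_idx, cfg, n_components=C)
        blocks.append(fmri_feats)
        standardize = standardize or cfg.standardize_fmri
    feats = blocks[0] if len(blocks) == 1 else ce.combine_features(*blocks)

    # kernel policy: linear for the non-linear texture features, RBF for
    # the linear time-course features, linear for the combination
    kernel = "rbf" if cfg.mode == "F" else "linear"
    spec = ce.ClassifierSpec(kernel=kernel, standardize=standardize)
    model = ce.train_svm(
        feats[train_idx], labels[train_idx], spec, cv_folds=cfg.cv_folds, seed=cfg.seed
    )
    pred = model.predict(feats[hold_idx])
    truth = labels[hold_idx]
    baseline = max(np.mean(truth == "case"), np.mean(truth == "control"))
    report = ce.evaluate_predictions(pred, truth, baseline_rate=float(baseline))

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "n_train": int(train_idx.size),
        "n_holdout": int(hold_idx.size),
        "n_components": n_comp_used,
        "gamma": model.gamma,
        "holdout_subjects_used_once": True,
    }
    result = PipelineResult(
        report=report,
        cv_accuracy=model.cv_accuracy,
        gamma=model.gamma,
        n_components=n_comp_used,
        predictions=pred,
        truth=truth,
        subject_ids=[cohort.frame.loc[i, "subject_id"] for i in hold_idx],
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_artifacts(result, cohort, hold_idx, cfg)
    return result


def _select_components(series, train_idx, labels, cfg: PipelineConfig) -> int:
    """Choose C from the grid by training-split CV accuracy."""
    best = None
    for C in cfg.component_grid:  # type: ignore[union-attr]
        feats, _, _ = fmri_feature_matrix(series, train_idx, cfg, n_components=C)
        spec = ce.ClassifierSpec(kernel="rbf", standardize=cfg.standardize_fmri)
        model = ce.train_svm(
            feats[train_idx], labels[train_idx], spec, cv_folds=cfg.cv_folds, seed=cfg.seed
        )
        if best is None or model.cv_accuracy > best[0]:
            best = (model.cv_accuracy, C)
    assert best is not None
    logger.info("component grid CV selected C=%d (cv acc %.4f)", best[1], best[0])
    return best[1]


def _write_artifacts(result: PipelineResult, cohort, hold_idx, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as f:
        json.dump(
            {
                **result.report.to_dict(),
                "cv_accuracy": result.cv_accuracy,
                "gamma": result.gamma,
            },
            f,
            indent=2,
        )
    with open(out / "manifest.json", "w") as f:
        json.dump(result.manifest, f, indent=2, default=str)
    with open(out / "predictions.tsv", "w") as f:
        f.write("subject_id\ttruth\tpred\tsplit\n")
        for sid, t, p in zip(result.subject_ids, result.truth, result.predictions):
            f.write(f"{sid}\t{t}\t{p}\tholdout\n")
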