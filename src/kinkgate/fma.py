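"""Functional mode analysis: the collective motion tracking an order parameter.

Partial-least-squares (PLS) regression of superposed backbone coordinates
against a scalar functional quantity — here, by default, the bending angle
of one designated inner helix — yields the single collective mode whose
motion is maximally correlated with that quantity.  The mode is
reconstructed into two extreme conformations (low/high percentiles of the
per-frame projection) which, on channel data, correspond to the kinked and
bent states of the helix.

Frames are time-correlated, so the default model validation uses a
contiguous-block train/validation split (random splits are over-optimistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory_io import FrameSeries, Topology, select

__all__ = [
    "FMAModel",
    "superpose",
    "kabsch_rotation",
    "fit_fma",
    "extreme_conformations",
    "cross_validate",
]


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix R (proper, det +1) minimising |R p - q|.

    P and Q are centred (n, 3) point sets.
    """
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    frames: FrameSeries,
    topology: Topology,
    reference_frame: int = 0,
    fit_expr: str = "backbone",
) -> FrameSeries:
    """Least-squares superpose every frame onto a reference (Kabsch).

    The optimal rigid motion is determined on ``fit_expr`` atoms and
    applied to all atoms.  Collinear fit selections are rejected.
    """
    sel = select(topology, fit_expr)
    if len(sel) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    ref = frames.coordinates[reference_frame, sel.indices, :]
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    out = np.empty_like(frames.coordinates)
    for f in range(frames.n_frames):
        mob = frames.coordinates[f, sel.indices, :]
        centroid = mob.mean(axis=0)
        R = kabsch_rotation(mob - centroid, ref_c)
        out[f] = (frames.coordinates[f] - centroid) @ R.T + ref_centroid
    return FrameSeries(frames.times.copy(), out, frames.box.copy())


@dataclass
class FMAModel:
    """Fitted PLS collective mode.

    ``mode`` is the unit coefficient vector over the 3N fitted coordinates;
    ``projections`` are per-frame scalar displacements of the centred
    coordinates along the mode (training mean at 0).
    """

    mean_structure: np.ndarray  # (N, 3) training-mean coordinates
    mode: np.ndarray  # (3N,), |mode| = 1
    n_components: int
    r_train: float
    r_valid: float
    projections: np.ndarray  # (n_frames,)
    train_slice: slice

    @property
    def fitted(self) -> bool:
        return self.mode is not None


def _pearson(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def fit_fma(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 1,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> FMAModel:
    """PLS regression of coordinates against the order parameter.

    X is (n_frames, 3N) superposed coordinates, y the per-frame functional
    quantity.  The first ``train_fraction`` of frames (a contiguous block)
    trains the model; the rest validates.  Deterministic: PLS has no random
    element and the split is contiguous (``seed`` is accepted for interface
    stability).
    """
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of frames")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite order parameter values")
    if np.std(y) == 0:
        raise ValueError("zero-variance order parameter")
    n_train = int(round(X.shape[0] * train_fraction))
    if n_components >= n_train:
        raise ValueError("n_components must be < number of training frames")
    tr = slice(0, n_train)
    va = slice(n_train, X.shape[0])
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X[tr], y[tr])
    coef = np.asarray(pls.coef_).reshape(-1)
    norm = np.linalg.norm(coef)
    if norm == 0:
        raise ValueError("degenerate PLS fit: zero coefficient vector")
    mode = coef / norm
    x_mean = X[tr].mean(axis=0)
    projections = (X - x_mean) @ mode
    pred_tr = pls.predict(X[tr]).ravel()
    pred_va = pls.predict(X[va]).ravel() if va.stop > va.start else np.array([])
    r_valid = _pearson(pred_va, y[va]) if pred_va.size > 1 else np.nan
    return FMAModel(
        mean_structure=x_mean.reshape(-1, 3),
        mode=mode,
        n_components=n_components,
        r_train=_pearson(pred_tr, y[tr]),
        r_valid=r_valid,
        projections=projections,
        train_slice=tr,
    )


def extreme_conformations(
    model: FMAModel, percentiles: tuple = (1.0, 99.0)
) -> tuple:
    """Structures at the low/high percentiles of the mode projection.

    Returns (low, high) as (N, 3) coordinate arrays: the training-mean
    structure displaced along the mode by the percentile projection.
    """
    if model.mode is None or model.projections is None:
        raise ValueError("model not fitted")
    q_lo, q_hi = np.percentile(model.projections, percentiles)
    disp = model.mode.reshape(-1, 3)
    return model.mean_structure + q_lo * disp, model.mean_structure + q_hi * disp


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    component_grid=(1, 2, 3, 4, 5),
    k_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Choose the PLS order by k-fold CV with the one-standard-error rule.

    Folds are contiguous frame blocks (time-aware).  The selected order is
    the smallest whose mean validation correlation is within one SEM of the
    best; a best correlation below 0.5 flags the whole selection as
    unreliable.  Deterministic given the inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n < 2 * k_folds:
        raise ValueError("too few frames for the requested folds")
    bounds = np.linspace(0, n, k_folds + 1).astype(int)
    results = {}
    for k in component_grid:
        rs = []
        for i in range(k_folds):
            va = np.arange(bounds[i], bounds[i + 1])
            tr = np.setdiff1d(np.arange(n), va)
            if k >= len(tr):
                rs.append(np.nan)
                continue
            from sklearn.cross_decomposition import PLSRegression

            pls = PLSRegression(n_components=k, scale=False)
            pls.fit(X[tr], y[tr])
            rs.append(_pearson(pls.predict(X[va]).ravel(), y[va]))
        rs = np.asarray(rs, dtype=float)
        results[k] = (
            float(np.nanmean(rs)),
            float(np.nanstd(rs, ddof=1) / np.sqrt(np.sum(np.isfinite(rs)))),
        )
    best_k = max(results, key=lambda k: results[k][0])
    best_mean, best_sem = results[best_k]
    chosen = min(
        (k for k in results if results[k][0] >= best_mean - best_sem),
        default=best_k,
    )
    return {
        "chosen_n_components": int(chosen),
        "per_component": results,
        "best_r_valid": best_mean,
        "reliable": bool(best_mean >= 0.5),
    }
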