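"""Classical comparison methods: GLM encoding, searchlight SVM decoding, and
whole-brain L1-regularized logistic decoding.

The GLM regresses each voxel's time series on HRF-convolved block regressors
(``Y = X beta + eps``) and tests the per-state coefficients. The searchlight
scans the brain with a sphere (default radius 5.6 mm) and maps the
cross-validated accuracy of a linear SVM on each sphere's voxels; the method's
overall accuracy is the maximum over locations, and decoding predictions come
from the best-location sphere. The whole-brain lasso minimizes the L1-penalized
logistic negative log-likelihood (one-vs-rest over states) by proximal
gradient descent with backtracking, giving sparse voxel coefficient maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .hrf import convolve_boxcar
from .io import DEFAULT_STATES, labels_from_events
from .preprocess import BrainMask

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GLM


@dataclass
class DesignMatrix:
    X: np.ndarray  # (T, P)
    names: list[str]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]


@dataclass
class GLMFit:
    beta: np.ndarray  # (P, N)
    residual_variance: np.ndarray  # (N,)
    t: np.ndarray  # (P, N)
    p: np.ndarray  # (P, N)
    dof: int
    names: list[str]


def build_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    hrf_peak_delay: float = 6.0,
    intercept: bool = True,
    state_names: tuple[str, ...] | None = None,
) -> DesignMatrix:
    """One HRF-convolved boxcar regressor per state, sampled at TRs."""
    if len(events) == 0:
        raise ValueError("empty events table")
    if state_names is None:
        seen = list(dict.fromkeys(events["trial_type"]))
        state_names = DEFAULT_STATES if set(seen) <= set(DEFAULT_STATES) else tuple(seen)
    labels = labels_from_events(events, n_volumes, tr, state_names)
    states = np.unique(labels[labels >= 0])
    names = [str(s) for s in state_names]
    columns = []
    used_names = []
    for k in states:
        boxcar = (labels == k).astype(float)
        columns.append(convolve_boxcar(boxcar, tr, peak_delay=hrf_peak_delay))
        used_names.append(names[k] if k < len(names) else f"state{k}")
    if intercept:
        columns.append(np.ones(n_volumes))
        used_names.append("intercept")
    return DesignMatrix(X=np.column_stack(columns), names=used_names)


def glm_fit(Y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Voxelwise ordinary least squares with per-predictor t and p values."""
    X = design.X
    T, P = X.shape
    if Y.shape[0] != T:
        raise ValueError("Y and design matrix row counts differ")
    if T <= P:
        raise ValueError("need more time points than predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < P:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {P}); "
            f"most collinear columns: {design.names[i]!r}, {design.names[j]!r}"
        )
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = T - P
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return GLMFit(
        beta=beta,
        residual_variance=sigma2,
        t=t,
        p=p,
        dof=dof,
        names=design.names,
    )


def fdr_threshold(p_values: np.ndarray, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at expected FDR ``q``."""
    p = np.asarray(p_values, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject.reshape(np.shape(p_values))


# ---------------------------------------------------------------------------
# whole-brain lasso


@dataclass
class LassoModel:
    beta: np.ndarray  # (K, N) one-vs-rest voxel coefficients
    intercept: np.ndarray  # (K,)
    lam: float
    objective_history: list[list[float]] = field(default_factory=list)
    converged: bool = True


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _nll(X: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float) -> float:
    eta = X @ beta + b0
    # -sum[y log sigma + (1-y) log(1-sigma)] in a numerically stable form
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _soft_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LassoModel:
    """L1-penalized logistic regression, one-vs-rest over classes.

    Proximal gradient (ISTA) with backtracking line search; the penalized
    objective ``NLL + lam * ||beta||_1`` (intercept unpenalized) is monotone
    non-increasing across iterations by construction of the line search.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    K = len(classes)
    T, N = X.shape
    beta = np.zeros((K, N))
    intercept = np.zeros(K)
    histories = []
    converged = True
    for ki, cls in enumerate(classes):
        yk = (y == cls).astype(float)
        b = np.zeros(N)
        b0 = 0.0
        step = 4.0 / max(np.linalg.norm(X, ord=2) ** 2 / T, 1e-12) / T  # ~1/L heuristic
        obj = _nll(X, yk, b, b0) + lam * np.abs(b).sum()
        history = [obj]
        it = 0
        for it in range(max_iter):
            eta = X @ b + b0
            mu = _logistic(eta)
            grad_b = X.T @ (mu - yk)
            grad_b0 = float(np.sum(mu - yk))
            # backtracking line search on the proximal step
            t_step = step
            for _ in range(60):
                b_new = _soft_threshold(b - t_step * grad_b, t_step * lam)
                b0_new = b0 - t_step * grad_b0
                obj_new = _nll(X, yk, b_new, b0_new) + lam * np.abs(b_new).sum()
                if obj_new <= obj + 1e-12:
                    break
                t_step *= 0.5
            else:  # pragma: no cover - pathological scaling
                b_new, b0_new, obj_new = b, b0, obj
            rel = abs(obj - obj_new) / max(abs(obj), 1.0)
            b, b0, obj = b_new, b0_new, obj_new
            history.append(obj)
            if rel < tol:
                break
        else:
            converged = False
            warnings.warn(
                f"lasso one-vs-rest class {cls}: not converged after {max_iter} "
                "iterations; returning best iterate",
                stacklevel=2,
            )
        beta[ki] = b
        intercept[ki] = b0
        histories.append(history)
    return LassoModel(
        beta=beta, intercept=intercept, lam=lam, objective_history=histories, converged=converged
    )


def lasso_predict(
    model: LassoModel, X: np.ndarray, return_probabilities: bool = False
):
    """Per-class logistic scores sigma(beta^T x + b); argmax label, low-index ties."""
    probs = _logistic(X @ model.beta.T + model.intercept)
    labels = np.argmax(probs, axis=1)
    if return_probabilities:
        return labels, probs
    return labels


def select_lambda(
    X_train, y_train, X_val, y_val, grid: list[float]
) -> tuple[float, LassoModel]:
    """Grid search on validation accuracy; smaller lambda wins ties."""
    best = None
    for lam in sorted(grid):
        model = lasso_fit(X_train, y_train, lam)
        acc = float(np.mean(lasso_predict(model, X_val) == y_val))
        if best is None or acc > best[0] + 1e-12:
            best = (acc, lam, model)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# searchlight


def sphere_offsets(radius_mm: float, voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Integer voxel offsets within radius_mm (Euclidean, in mm) of a center."""
    reach = [int(np.floor(radius_mm / vs)) for vs in voxel_size]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in reach], indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.sqrt(((offs * np.asarray(voxel_size)) ** 2).sum(axis=1))
    return offs[dist <= radius_mm + 1e-9]


def _sphere_accuracy(
    features: np.ndarray, labels: np.ndarray, folds: int, seed: int
) -> tuple[float, np.ndarray]:
    """Stratified k-fold CV accuracy of a linear SVM; also CV predictions."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(len(labels), dtype=int)
    for train_idx, test_idx in skf.split(features, labels):
        clf = LinearSVC(dual=True, max_iter=5000, random_state=seed)
        clf.fit(features[train_idx], labels[train_idx])
        preds[test_idx] = clf.predict(features[test_idx])
    return float(np.mean(preds == labels)), preds


@dataclass
class SearchlightResult:
    accuracy_map: np.ndarray  # (X, Y, Z), NaN where no sphere was evaluated
    best_location: tuple[int, int, int]
    best_accuracy: float
    best_predictions: np.ndarray
    radius_mm: float


def searchlight_map(
    volumes: np.ndarray,
    labels: np.ndarray,
    mask: BrainMask | None = None,
    radius_mm: float = 5.6,
    voxel_size=(2.0, 2.0, 2.0),
    folds: int = 5,
    seed: int = 0,
) -> SearchlightResult:
    """Cross-validated linear-SVM accuracy at every in-mask sphere location.

    ``volumes``: (n_samples, X, Y, Z) task samples; spheres are all voxels
    within ``radius_mm`` of the center (brute-force offset enumeration),
    intersected with the mask. Spheres with fewer than 2 voxels are recorded
    as missing (NaN). Ties for the best location go to the lowest linear
    voxel index.
    """
    n_samples, *shape = volumes.shape
    shape = tuple(shape)
    if mask is None:
        mask = BrainMask.full(shape)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    offs = sphere_offsets(radius_mm, voxel_size)
    flat = volumes.reshape(n_samples, -1)
    acc_map = np.full(shape, np.nan)
    best = (-1.0, None, None)
    centers = np.argwhere(mask.mask)
    for cx, cy, cz in centers:
        coords = offs + np.array([cx, cy, cz])
        ok = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
        coords = coords[ok]
        inmask = mask.mask[coords[:, 0], coords[:, 1], coords[:, 2]]
        coords = coords[inmask]
        if len(coords) < 2:
            continue
        lin = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), shape)
        acc, preds = _sphere_accuracy(flat[:, lin], labels, folds, seed)
        acc_map[cx, cy, cz] = acc
        if acc > best[0]:
            best = (acc, (int(cx), int(cy), int(cz)), preds)
    if best[1] is None:
        raise ValueError("no sphere with at least 2 voxels inside the mask")
    return SearchlightResult(
        accuracy_map=acc_map,
        best_location=best[1],
        best_accuracy=best[0],
        best_predictions=best[2],
        radius_mm=radius_mm,
    )


def searchlight_decode(result: SearchlightResult) -> tuple[float, np.ndarray]:
    """The method's overall accuracy = maximum over locations; predictions
    come from the best-location sphere's cross-validated classifier."""
    return result.best_accuracy, result.best_predictions
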