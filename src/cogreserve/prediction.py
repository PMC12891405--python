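"""Stacked, nested cross-validated elastic-net prediction of a target score.

The first level fits, per feature block, a linear model with a combined L1 +
L2 (elastic-net) penalty inside nested cross-validation: outer folds produce
out-of-fold predictions, inner folds select the penalty pair.  The second
level stacks block predictions with a nonnegative least-squares model that is
itself cross-fitted over the outer folds, so stacked predictions remain
strictly out-of-sample.

Leakage discipline: standardization statistics (per-feature mean/SD, target
mean), penalty selection, model coefficients and stacking weights are all
estimated on training subjects only and applied to held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.optimize import nnls
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from cogreserve.synthetic import FeatureBlock

__all__ = [
    "CVConfig",
    "BlockPrediction",
    "StackResult",
    "default_penalty_grid",
    "fit_block_model",
    "stack",
    "cross_validated_r2",
    "outer_fold_labels",
]


def default_penalty_grid() -> tuple:
    """Grid over L1 mixing weight {0.01, 0.25, 0.5, 0.75, 1.0} crossed with
    20 log-spaced total penalty strengths (1e-2 .. 10)."""
    strengths = np.logspace(-2, 1, 20)
    return tuple(
        (l1, float(a)) for l1 in (0.01, 0.25, 0.5, 0.75, 1.0) for a in strengths
    )


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation settings.

    ``n_repeats`` re-randomizes the outer fold assignment; across-repeat
    spread provides the error bars of the variance-partition staircase.
    """

    n_outer_folds: int = 10
    n_inner_folds: int = 5
    penalty_grid: tuple = field(default_factory=default_penalty_grid)
    n_repeats: int = 20
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("outer and inner fold counts must be >= 2")
        if len(self.penalty_grid) == 0:
            raise ValueError("penalty_grid must be non-empty")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        grid = tuple((float(l1), float(a)) for l1, a in self.penalty_grid)
        for l1, a in grid:
            if not 0.0 <= l1 <= 1.0:
                raise ValueError(f"l1_weight {l1} outside [0, 1]")
            if a < 0:
                raise ValueError(f"penalty strength {a} must be >= 0")
        object.__setattr__(self, "penalty_grid", grid)


@dataclass(frozen=True)
class BlockPrediction:
    """Out-of-fold predictions of one block for one repeat."""

    block_name: str
    oof_pred: np.ndarray
    chosen_penalties: tuple  # (l1_weight, strength) per outer fold
    repeat_index: int
    fold_labels: np.ndarray  # outer fold id per subject


@dataclass(frozen=True)
class StackResult:
    """Cross-fitted stacked prediction over an ordered set of blocks."""

    included_blocks: tuple
    oof_pred: np.ndarray
    stack_weights: tuple  # per outer fold: (intercept, w_1..w_B)
    repeat_index: int
    fold_labels: np.ndarray


def outer_fold_labels(n: int, n_folds: int, seed: int, repeat: int) -> np.ndarray:
    """Deterministic outer fold assignment for (seed, repeat).

    A seeded permutation split into ``n_folds`` contiguous chunks; fold sizes
    differ by at most one and the folds partition the subjects.
    """
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {n}")
    rng = np.random.default_rng([seed, repeat])
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, n_folds)):
        labels[chunk] = k
    return labels


def _column_standardizer(X: np.ndarray, standardize: bool):
    """Training-set mean/scale; binary columns are centred but not scaled."""
    mean = X.mean(axis=0)
    if not standardize:
        return mean, np.ones(X.shape[1])
    scale = X.std(axis=0)
    for j in range(X.shape[1]):
        if np.unique(X[:, j]).size <= 2:
            scale[j] = 1.0
    scale[scale == 0] = 1.0
    return mean, scale


def _solve_penalized(X: np.ndarray, y: np.ndarray, l1_weight: float, strength: float) -> np.ndarray:
    """Minimize (1/2n)||y - Xb||^2 + strength*(l1*||b||_1 + (1-l1)/2*||b||^2).

    Pure-L2 candidates are solved exactly through the penalized normal
    equations; mixed penalties use coordinate descent.
    """
    n = X.shape[0]
    if l1_weight == 0.0:
        gram = X.T @ X / n + strength * np.eye(X.shape[1])
        return np.linalg.solve(gram, X.T @ y / n)
    model = ElasticNet(
        alpha=strength, l1_ratio=l1_weight, fit_intercept=False,
        max_iter=10_000, tol=1e-8,
    )
    model.fit(X, y)
    return model.coef_


def _path_coefs(X: np.ndarray, y: np.ndarray, l1_weight: float, alphas_desc: np.ndarray) -> np.ndarray:
    """Coefficients (p, n_alphas) for a descending strength path at one mixing
    weight, in the order of ``alphas_desc``."""
    if l1_weight == 0.0:
        # shared eigendecomposition makes the ridge path cheap
        n, p = X.shape
        w, v = np.linalg.eigh(X.T @ X / n)
        xty = v.T @ (X.T @ y / n)
        return np.column_stack([v @ (xty / (w + a)) for a in alphas_desc])
    with warnings.catch_warnings():
        # near-duplicate features make the smallest grid penalties converge
        # slowly; path accuracy at sklearn's default tol suffices for the
        # inner-CV comparison of candidates
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            X, y, l1_ratio=l1_weight, alphas=alphas_desc, max_iter=3000, tol=1e-4,
        )
    return coefs  # enet_path evaluates the given alphas in descending order


def _select_penalty(
    X: np.ndarray, y: np.ndarray, cv: CVConfig, seed_key: list,
) -> tuple:
    """Inner-CV penalty selection: mean validation squared error over the
    grid; ties broken toward the stronger total penalty."""
    if len(cv.penalty_grid) == 1:
        return cv.penalty_grid[0]
    n = X.shape[0]
    labels = outer_fold_labels(n, cv.n_inner_folds, seed_key[0], seed_key[1])

    by_l1: dict[float, list[float]] = {}
    for l1, a in cv.penalty_grid:
        by_l1.setdefault(l1, []).append(a)

    sse = {cand: 0.0 for cand in cv.penalty_grid}
    for k in range(cv.n_inner_folds):
        tr, va = labels != k, labels == k
        mean, scale = _column_standardizer(X[tr], cv.standardize)
        Xtr = (X[tr] - mean) / scale
        Xva = (X[va] - mean) / scale
        y_mean = y[tr].mean()
        ytr = y[tr] - y_mean
        yva = y[va] - y_mean
        for l1, alphas in by_l1.items():
            alphas_desc = np.sort(np.asarray(alphas))[::-1]
            coefs = _path_coefs(Xtr, ytr, l1, alphas_desc)
            resid = yva[:, None] - Xva @ coefs
            for a, col in zip(alphas_desc, resid.T):
                sse[(l1, float(a))] += float(col @ col)

    best = min(sse.values())
    tied = [cand for cand, v in sse.items() if v <= best + 1e-12]
    return max(tied, key=lambda cand: (cand[1], cand[0]))


def fit_block_model(
    block: FeatureBlock | np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    repeat: int = 0,
    block_name: str | None = None,
) -> BlockPrediction:
    """Nested-CV elastic net for one feature block.

    Outer folds (seeded by ``(cv.seed, repeat)``) partition the subjects;
    within each outer training set the inner CV picks the penalty pair, the
    model is refit on the whole outer training set, and the held-out fold is
    predicted.  Every subject is predicted exactly once, by a model that
    never saw it.
    """
    if isinstance(block, FeatureBlock):
        X, name = block.matrix, block.name
    else:
        X = np.asarray(block, dtype=float)
        name = block_name or "block"
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(y) == 0:
        raise ValueError("constant target; cross-validated R2 is undefined")

    n = y.size
    labels = outer_fold_labels(n, cv.n_outer_folds, cv.seed, repeat)
    oof = np.empty(n)
    chosen = []
    for k in range(cv.n_outer_folds):
        tr, te = labels != k, labels == k
        penalty = _select_penalty(X[tr], y[tr], cv, seed_key=[cv.seed, repeat * cv.n_outer_folds + k + 1])
        mean, scale = _column_standardizer(X[tr], cv.standardize)
        Xtr = (X[tr] - mean) / scale
        y_mean = y[tr].mean()
        coef = _solve_penalized(Xtr, y[tr] - y_mean, *penalty)
        oof[te] = ((X[te] - mean) / scale) @ coef + y_mean
        chosen.append(penalty)
    return BlockPrediction(
        block_name=name,
        oof_pred=oof,
        chosen_penalties=tuple(chosen),
        repeat_index=repeat,
        fold_labels=labels,
    )


def _nnls_affine(P: np.ndarray, y: np.ndarray) -> tuple:
    """Nonnegative least squares with a free intercept (columns centred)."""
    p_mean = P.mean(axis=0)
    y_mean = y.mean()
    w, _ = nnls(P - p_mean, y - y_mean)
    return float(y_mean - w @ p_mean), w


def stack(
    preds: list,
    y: np.ndarray,
    cv: CVConfig,
    repeat: int = 0,
) -> StackResult:
    """Cross-fitted nonnegative stacking of block out-of-fold predictions.

    For each outer fold the level-2 model (NNLS with intercept) is fit on the
    remaining folds' out-of-fold predictions and applied to the held-out
    fold.  With a single block this reduces to an affine recalibration of
    that block's prediction.
    """
    if len(preds) == 0:
        raise ValueError("need at least one block prediction")
    y = np.asarray(y, dtype=float).ravel()
    labels = preds[0].fold_labels
    for bp in preds:
        if bp.repeat_index != repeat:
            raise ValueError(
                f"prediction for block {bp.block_name!r} is from repeat "
                f"{bp.repeat_index}, expected {repeat}"
            )
        if not np.array_equal(bp.fold_labels, labels):
            raise ValueError(
                f"block {bp.block_name!r} used a different fold assignment; "
                "stacking them would leak information"
            )
        if bp.oof_pred.size != y.size:
            raise ValueError("prediction length does not match target length")

    P = np.column_stack([bp.oof_pred for bp in preds])
    n_folds = labels.max() + 1
    oof = np.empty(y.size)
    weights = []
    for k in range(n_folds):
        tr, te = labels != k, labels == k
        intercept, w = _nnls_affine(P[tr], y[tr])
        oof[te] = intercept + P[te] @ w
        weights.append((intercept, *w))
    return StackResult(
        included_blocks=tuple(bp.block_name for bp in preds),
        oof_pred=oof,
        stack_weights=tuple(weights),
        repeat_index=repeat,
        fold_labels=labels,
    )


def cross_validated_r2(y: np.ndarray, oof_pred: np.ndarray) -> float:
    """Out-of-sample R^2 against the full-sample mean benchmark.

    ``1 - SS_res / SS_tot``; negative for predictors worse than the mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    oof_pred = np.asarray(oof_pred, dtype=float).ravel()
    if y.size != oof_pred.size:
        raise ValueError("length mismatch between target and predictions")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant target; R2 is undefined")
    ss_res = float(np.sum((y - oof_pred) ** 2))
    return 1.0 - ss_res / ss_tot
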