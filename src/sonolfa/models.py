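"""KNN classification and Gaussian-process regression on RGB features.

Both models are implemented directly (dense linear algebra via scipy)
rather than wrapped from a fitting library, so their behavior — the KNN
tie-breaking rules, the exact marginal-likelihood objective — is pinned
by this module's contracts and checked against independent oracles in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "KnnModel",
    "GprModel",
    "CvSplit",
    "knn_fit",
    "knn_predict",
    "gpr_fit",
    "gpr_predict",
    "kfold_split",
    "cross_validate",
    "CvResult",
]

_JITTER = 1e-10


# ---------------------------------------------------------------------------
# KNN

@dataclass
class KnnModel:
    """k-nearest-neighbor classifier state (plain Euclidean metric)."""

    train_rgb: np.ndarray  # (n, 3)
    train_labels: np.ndarray  # (n,)
    k: int = 5

    def __post_init__(self) -> None:
        self.train_rgb = np.asarray(self.train_rgb, dtype=float)
        self.train_labels = np.asarray(self.train_labels)
        if self.train_rgb.ndim != 2 or self.train_rgb.shape[0] == 0:
            raise ValueError("train_rgb must be a non-empty 2D array")
        if self.train_labels.shape[0] != self.train_rgb.shape[0]:
            raise ValueError("labels and features disagree on n")
        if not (1 <= self.k <= self.train_rgb.shape[0]):
            raise ValueError("k must satisfy 1 <= k <= n")


def knn_fit(train_rgb: np.ndarray, train_labels: np.ndarray, k: int = 5) -> KnnModel:
    return KnnModel(train_rgb=train_rgb, train_labels=train_labels, k=k)


def knn_predict(model: KnnModel, query_rgb: np.ndarray):
    """Majority vote over the k nearest training points.

    Ties between classes are broken by the smaller summed distance of
    each tied class's neighbors, then by the label of the single nearest
    neighbor.  Accepts one query (returns a scalar label) or a stack of
    queries (returns an array).
    """
    q = np.asarray(query_rgb, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    dists = np.sqrt(((q[:, None, :] - model.train_rgb[None, :, :]) ** 2).sum(axis=2))
    out = []
    for row in dists:
        order = np.argsort(row, kind="stable")
        nearest = order[: model.k]
        labels = model.train_labels[nearest]
        classes, votes = np.unique(labels, return_counts=True)
        top = classes[votes == votes.max()]
        if top.size == 1:
            out.append(top[0])
            continue
        sums = {c: row[nearest[labels == c]].sum() for c in top}
        best = min(sums.values())
        tied = [c for c in top if sums[c] == best]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            out.append(model.train_labels[order[0]])
    result = np.array(out)
    return result[0] if single else result


# ---------------------------------------------------------------------------
# GPR

@dataclass
class GprModel:
    """RBF-kernel Gaussian-process regressor with a white-noise term.

    Features are standardized internally (transform stored on the model);
    targets are fit on their raw scale.  ``cached_solve`` holds the
    Cholesky factor of K + sigma_n^2 I over the training inputs.
    """

    train_rgb: np.ndarray
    train_conc: np.ndarray
    signal_variance: float
    length_scale: float
    noise_variance: float
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0
    cached_solve: tuple = field(repr=False, default=None)


def _rbf(a: np.ndarray, b: np.ndarray, sf2: float, ls: float) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return sf2 * np.exp(-0.5 * d2 / ls**2)


def log_marginal_likelihood(
    x: np.ndarray, y: np.ndarray, sf2: float, ls: float, sn2: float
) -> float:
    """-1/2 y^T (K+sn2 I)^-1 y - 1/2 log|K+sn2 I| - (n/2) log 2 pi."""
    n = x.shape[0]
    ky = _rbf(x, x, sf2, ls) + (sn2 + _JITTER) * np.eye(n)
    try:
        chol = linalg.cholesky(ky, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("kernel matrix singular after jitter") from exc
    alpha = linalg.cho_solve((chol, True), y)
    return float(
        -0.5 * y @ alpha - np.log(np.diag(chol)).sum() - 0.5 * n * math.log(2.0 * math.pi)
    )


def gpr_fit(
    train_rgb: np.ndarray,
    train_conc: np.ndarray,
    optimize_hyperparams: bool = True,
    restarts: int = 3,
    seed: int = 0,
    signal_variance: float = 1.0,
    length_scale: float = 1.0,
    noise_variance: float = 1e-4,
) -> GprModel:
    """Fit the GP, optionally maximizing the log marginal likelihood.

    Hyperparameters are searched in log space with L-BFGS-B from
    ``restarts + 1`` deterministic seeded starting points; the best
    optimum wins.  The fitted target is centered; the prior mean on the
    original scale is the training-target mean.
    """
    x = np.atleast_2d(np.asarray(train_rgb, dtype=float))
    y = np.asarray(train_conc, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and targets disagree on n")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training points")

    x_mean = x.mean(axis=0)
    x_scale = x.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    xs = (x - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    theta = np.log(np.maximum([signal_variance, length_scale, noise_variance], 1e-300))
    if optimize_hyperparams:
        rng = np.random.default_rng(seed)
        y_var = max(float(yc.var()), 1e-12)
        starts = [np.log([y_var, 1.0, max(1e-6 * y_var, 1e-10)])]
        for _ in range(restarts):
            starts.append(
                np.array(
                    [
                        math.log(y_var) + rng.uniform(-2, 2),
                        rng.uniform(math.log(0.1), math.log(10.0)),
                        math.log(y_var) + rng.uniform(-14, -2),
                    ]
                )
            )

        def neg_lml(t: np.ndarray) -> float:
            sf2, ls, sn2 = np.exp(t)
            try:
                return -log_marginal_likelihood(xs, yc, sf2, ls, sn2)
            except (ValueError, FloatingPointError):
                return 1e25

        best = None
        for t0 in starts:
            res = optimize.minimize(
                neg_lml,
                t0,
                method="L-BFGS-B",
                bounds=[(-20.0, 20.0), (-8.0, 8.0), (-30.0, 10.0)],
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
    sf2, ls, sn2 = (float(v) for v in np.exp(theta))

    n = xs.shape[0]
    ky = _rbf(xs, xs, sf2, ls) + (sn2 + _JITTER) * np.eye(n)
    try:
        chol = linalg.cholesky(ky, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("kernel matrix singular after jitter") from exc
    alpha = linalg.cho_solve((chol, True), yc)

    return GprModel(
        train_rgb=xs,
        train_conc=yc,
        signal_variance=sf2,
        length_scale=ls,
        noise_variance=sn2,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        cached_solve=(chol, alpha),
    )


def gpr_predict(model: GprModel, query_rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at the query points.

    mean = k*^T (K + sn2 I)^-1 y (plus the prior mean);
    var = k(q,q) - k*^T (K + sn2 I)^-1 k*, clipped at zero.
    """
    if model.cached_solve is None:
        raise ValueError("model is not fitted")
    q = np.atleast_2d(np.asarray(query_rgb, dtype=float))
    qs = (q - model.x_mean) / model.x_scale
    chol, alpha = model.cached_solve
    k_star = _rbf(qs, model.train_rgb, model.signal_variance, model.length_scale)
    mean = k_star @ alpha + model.y_mean
    v = linalg.solve_triangular(chol, k_star.T, lower=True)
    var = model.signal_variance - (v**2).sum(axis=0)
    if np.any(var < -1e-9):
        import warnings

        warnings.warn("posterior variance below -1e-9 before clipping", RuntimeWarning)
    return mean, np.clip(var, 0.0, None)


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CvSplit:
    """Assignment of each sample index to one of ``n_folds`` folds."""

    fold_of: np.ndarray
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def kfold_split(
    labels: np.ndarray, n_folds: int = 5, stratify: bool = True, seed: int = 0
) -> CvSplit:
    """Random (optionally stratified) k-fold partition.

    Fold sizes differ by at most one; with stratification, per-class
    counts per fold also differ by at most one.  Deterministic in
    ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < n_folds:
        raise ValueError("need at least n_folds samples")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratify:
        offset = 0
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < n_folds:
                raise ValueError(
                    f"class {cls!r} has {idx.size} members, fewer than {n_folds} folds"
                )
            perm = rng.permutation(idx)
            # rotate the starting fold per class to balance overall sizes
            folds = (np.arange(perm.size) + offset) % n_folds
            fold_of[perm] = folds
            offset = (offset + idx.size) % n_folds
    else:
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % n_folds
    return CvSplit(fold_of=fold_of, n_folds=n_folds, seed=seed)


@dataclass
class CvResult:
    """Pooled out-of-fold predictions, aligned with the input order."""

    predictions: np.ndarray
    truths: np.ndarray
    split: CvSplit


def cross_validate(
    features: np.ndarray,
    targets: np.ndarray,
    model_kind: str,
    n_folds: int = 5,
    seed: int = 0,
    k: int = 5,
    gpr_restarts: int = 2,
) -> CvResult:
    """Out-of-fold predictions: each sample predicted exactly once by a
    model not trained on it.

    ``model_kind`` is ``"knn"`` (stratified folds, class targets) or
    ``"gpr"`` (plain random folds, continuous targets).
    """
    if model_kind not in ("knn", "gpr"):
        raise ValueError("model_kind must be 'knn' or 'gpr'")
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets)
    split = kfold_split(targets, n_folds=n_folds, stratify=model_kind == "knn", seed=seed)
    preds = np.empty(targets.shape[0], dtype=float if model_kind == "gpr" else targets.dtype)
    for fold in range(n_folds):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        if model_kind == "knn":
            model = knn_fit(features[tr], targets[tr], k=min(k, tr.size))
            preds[te] = knn_predict(model, features[te])
        else:
            model = gpr_fit(
                features[tr],
                targets[tr].astype(float),
                restarts=gpr_restarts,
                seed=seed + fold,
            )
            preds[te], _ = gpr_predict(model, features[te])
    return CvResult(predictions=preds, truths=targets, split=split)
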