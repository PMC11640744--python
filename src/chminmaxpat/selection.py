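"""Cumulative-weight NCA (CWNCA) feature selection.

Feature relevance weights come from diagonal-metric neighbourhood component
analysis (NCA) feature weighting: each feature j carries a weight w_j, the
dissimilarity between samples i and i' is the weighted city-block distance
sum_j w_j^2 |x_ij - x_i'j| / sigma, and the stochastic-neighbour
probabilities p_ii' built from it give an expected leave-one-out
correct-classification objective

    F(w) = sum_i p_i - lambda * sum_j w_j^2,
    p_i  = sum_{i' != i, y_i' = y_i} p_ii',

maximized over w by gradient ascent.  Selection then sorts features by
descending weight and keeps the smallest prefix whose normalized cumulative
weight reaches a threshold (default 0.99).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Above this many pairwise-difference elements the gradient loop recomputes
#: per-feature |x_i - x_j| chunks on the fly instead of caching them.
_CACHE_ELEMENT_LIMIT = 200_000_000
_CHUNK = 256


@dataclass(frozen=True, eq=False)
class SelectionResult:
    """NCA weights with the cumulative-weight cut for one feature vector."""

    weights: np.ndarray          # nonnegative, one per feature
    order: np.ndarray            # 0-based feature indices, descending weight
    nf: int                      # number of selected features
    threshold: float

    @property
    def selected_indices(self) -> np.ndarray:
        """The first ``nf`` indices of ``order`` (0-based, descending weight)."""
        return self.order[: self.nf]


def nca_objective_grad(
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    sigma: float = 1.0,
    lam: float = 0.0,
    _cache: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Objective F(w) and its gradient for NCA feature weighting.

    ``X`` is used as given (no standardization here).  Exposed separately so
    the gradient can be validated against finite differences.  ``_cache``
    lets a caller reuse the precomputed pairwise-difference table across
    iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, nfeat = X.shape
    w = np.asarray(w, dtype=float)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    w2 = w * w
    cache = _absdiff_cache(X) if _cache is None else _cache
    D = _weighted_cityblock(X, w2, cache) / sigma
    # softmax over i' != i with the diagonal excluded
    np.fill_diagonal(D, np.inf)
    D -= D.min(axis=1, keepdims=True)
    P = np.exp(-D)
    np.fill_diagonal(P, 0.0)
    denom = P.sum(axis=1, keepdims=True)
    denom[denom == 0.0] = 1.0
    P /= denom
    p_i = (P * same).sum(axis=1)

    obj = float(p_i.sum() - lam * np.dot(w, w))
    # coef_ij = p_i * p_ij - p_ij * [y_j == y_i]
    coef = P * (p_i[:, None] - same)
    grad = (2.0 / sigma) * w * _coef_dot_absdiff(X, coef, cache) - 2.0 * lam * w
    return obj, grad


def _absdiff_cache(X: np.ndarray) -> np.ndarray | None:
    n, nfeat = X.shape
    size = n * n * nfeat
    if size > _CACHE_ELEMENT_LIMIT:
        return None
    # float32 halves memory on big problems; small ones keep full precision
    dtype = np.float64 if size <= 20_000_000 else np.float32
    A = np.abs(X[:, None, :] - X[None, :, :]).astype(dtype)
    return A.reshape(n * n, nfeat)


def _weighted_cityblock(X: np.ndarray, w2: np.ndarray, cache: np.ndarray | None) -> np.ndarray:
    n, nfeat = X.shape
    if cache is not None:
        return (cache @ w2.astype(cache.dtype)).astype(float).reshape(n, n)
    D = np.zeros((n, n))
    for lo in range(0, nfeat, _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        A = np.abs(X[:, None, sl] - X[None, :, sl])
        D += A @ w2[sl]
    return D


def _coef_dot_absdiff(X: np.ndarray, coef: np.ndarray, cache: np.ndarray | None) -> np.ndarray:
    n, nfeat = X.shape
    if cache is not None:
        return (coef.reshape(-1).astype(cache.dtype) @ cache).astype(float)
    out = np.empty(nfeat)
    flat = coef.reshape(-1)
    for lo in range(0, nfeat, _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        A = np.abs(X[:, None, sl] - X[None, :, sl]).reshape(n * n, -1)
        out[sl] = flat @ A
    return out


def nca_weights(
    features: np.ndarray,
    labels: np.ndarray,
    sigma: float = 1.0,
    lam: float | None = None,
    iters: int = 100,
    lr: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Fit NCA feature weights by gradient ascent from the all-ones vector.

    Features are z-scored internally; zero-variance columns are dropped from
    the fit and returned with weight 0.  ``lam`` defaults to 1/n_samples.
    The step size starts at ``lr`` and adapts multiplicatively: an
    objective-improving step is accepted (lr grows 1.1x), a worsening one is
    rejected (lr halves); ascent stops after ``iters`` iterations or when
    the gradient or step size becomes negligible.  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("feature matrix must be 2-D and non-empty")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to compute NCA weights")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    n, nfeat = X.shape
    if lam is None:
        lam = 1.0 / n

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    weights = np.zeros(nfeat)
    if not keep.any():
        logger.warning("all features have zero variance; returning zero weights")
        return weights

    w = np.ones(keep.sum())
    cache = _absdiff_cache(Z)
    obj, grad = nca_objective_grad(w, Z, y, sigma=sigma, lam=lam, _cache=cache)
    step = lr
    for _ in range(iters):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-9 or step < 1e-10:
            break
        w_new = w + step * grad
        obj_new, grad_new = nca_objective_grad(w_new, Z, y, sigma=sigma, lam=lam, _cache=cache)
        if obj_new > obj:
            w, obj, grad = w_new, obj_new, grad_new
            step *= 1.1
        else:
            step *= 0.5
    weights[keep] = np.clip(w, 0.0, None)
    return weights


def cumulative_select(weights: np.ndarray, threshold: float = 0.99) -> SelectionResult:
    """Keep the smallest descending-weight prefix reaching the cumulative threshold.

    Ties sort by lower feature index first.  All-zero weights fall back to
    selecting the single first feature (with a warning).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-D vector")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = np.argsort(-w, kind="stable")
    total = w.sum()
    if total <= 0:
        logger.warning("all NCA weights are zero; falling back to selecting one feature")
        return SelectionResult(weights=w, order=order, nf=1, threshold=threshold)
    cum = np.cumsum(w[order]) / total
    # tiny numerical grace so that e.g. an exact-1.0 cumulative sum passes
    nf = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    nf = min(nf, w.size)
    return SelectionResult(weights=w, order=order, nf=nf, threshold=threshold)


def apply_selection(features: np.ndarray, sel: SelectionResult) -> np.ndarray:
    """Subset/reorder columns to the selected indices in descending-weight order.

    This column order also defines the symbol order of the DLob string built
    from the same selection.
    """
    X = np.asarray(features)
    idx = sel.selected_indices
    if idx.max() >= X.shape[1] or idx.min() < 0:
        raise IndexError("selected index out of range for feature matrix")
    return X[:, idx]
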