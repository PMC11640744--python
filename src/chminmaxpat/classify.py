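"""tkNN: iterative/ensemble kNN with majority-vote fusion and greedy selection.

One "outcome" is a full-length out-of-fold prediction vector assembled
across all cross-validation folds, together with its accuracy against the
true labels.  Per feature vector, 60 parameter-based outcomes are generated
(k = 1..10 x {cityblock, euclidean, cosine} x {inverse, equal} weighting),
iterative majority voting (IMV) adds 58 voted outcomes (elementwise mode of
the top r+2 accuracy-sorted outcomes, r = 1..58), and a greedy pass keeps
the single most accurate of the 118.  Fusion across the 15 per-feature-
vector outcomes applies IMV again (13 voted outcomes) and greedily picks
the best voted outcome.  Accuracy-driven selection against the full label
vector is the pipeline's self-organization mechanism; it is deliberately
optimistic and is reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .eeg_data import DatasetManifest, FoldPlan

K_RANGE = tuple(range(1, 11))
DISTANCES = ("cityblock", "euclidean", "cosine")
WEIGHTINGS = ("inverse", "equal")
_INV_DELTA = 1e-12


@dataclass(frozen=True)
class KnnConfig:
    """One cell of the kNN parameter grid."""

    k: int
    distance: str
    weighting: str

    def __post_init__(self) -> None:
        if self.k not in K_RANGE:
            raise ValueError(f"k must be in {K_RANGE[0]}..{K_RANGE[-1]}, got {self.k}")
        if self.distance not in DISTANCES:
            raise ValueError(f"distance must be one of {DISTANCES}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")

    def __str__(self) -> str:
        return f"k={self.k},{self.distance},{self.weighting}"


@dataclass(frozen=True, eq=False)
class Outcome:
    """A full-length prediction vector with its accuracy and provenance."""

    predictions: np.ndarray
    accuracy: float
    provenance: str


def knn_grid() -> list[KnnConfig]:
    """The full 60-cell grid: k outermost, then distance, then weighting."""
    return [
        KnnConfig(k=k, distance=d, weighting=w)
        for k in K_RANGE
        for d in DISTANCES
        for w in WEIGHTINGS
    ]


def _distances(test: np.ndarray, train: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        with np.errstate(invalid="ignore", divide="ignore"):
            D = cdist(test, train, metric="cosine")
        # cosine similarity is undefined for zero vectors; define distance 1
        return np.nan_to_num(D, nan=1.0)
    return cdist(test, train, metric=metric)


def _predict_sorted(
    sorted_labels: np.ndarray,
    sorted_dists: np.ndarray,
    k: int,
    weighting: str,
    classes: tuple[int, int],
) -> np.ndarray:
    """Predictions given neighbour labels/distances pre-sorted by distance.

    Vote ties resolve to the single nearest neighbour's class (the
    remaining lower-label rule is unreachable with a defined nearest
    neighbour but kept as documentation of the contract).
    """
    lo, hi = classes
    lab_k = sorted_labels[:, :k]
    if weighting == "equal":
        s_lo = (lab_k == lo).sum(axis=1).astype(float)
        s_hi = (lab_k == hi).sum(axis=1).astype(float)
    else:
        wts = 1.0 / np.maximum(sorted_dists[:, :k], _INV_DELTA)
        s_lo = ((lab_k == lo) * wts).sum(axis=1)
        s_hi = ((lab_k == hi) * wts).sum(axis=1)
    nearest = sorted_labels[:, 0]
    return np.where(s_lo > s_hi, lo, np.where(s_hi > s_lo, hi, nearest))


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    cfg: KnnConfig,
) -> np.ndarray:
    """kNN prediction for one parameter configuration.

    Distance ties rank by lower training index; vote/score ties fall back
    to the nearest neighbour's class.
    """
    train = np.atleast_2d(np.asarray(train_features, dtype=float))
    test = np.atleast_2d(np.asarray(test_features, dtype=float))
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training labels must contain exactly two classes")
    if cfg.k > len(y):
        raise ValueError(f"k={cfg.k} exceeds the {len(y)} training samples")
    if test.shape[0] == 0:
        raise ValueError("empty test set")
    D = _distances(test, train, cfg.distance)
    order = np.argsort(D, axis=1, kind="stable")
    sl = y[order]
    sd = np.take_along_axis(D, order, axis=1)
    return _predict_sorted(sl, sd, cfg.k, cfg.weighting, (int(classes[0]), int(classes[1])))


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.asarray(predictions) == np.asarray(labels)))


def parameter_outcomes(
    features: np.ndarray,
    labels: np.ndarray,
    folds: FoldPlan,
    manifest: DatasetManifest,
) -> list[Outcome]:
    """Out-of-fold prediction vectors for all 60 kNN parameter configurations."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    classes = (int(classes[0]), int(classes[1]))
    grid = knn_grid()
    preds = {(c.k, c.distance, c.weighting): np.empty(n, dtype=y.dtype) for c in grid}
    all_idx = np.arange(n)
    for fold, test_idx in enumerate(folds.test_indices(manifest)):
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold}: training part lacks one of the classes")
        if max(K_RANGE) > len(train_idx):
            raise ValueError(f"fold {fold}: fewer training samples than k={max(K_RANGE)}")
        for metric in DISTANCES:
            D = _distances(X[test_idx], X[train_idx], metric)
            order = np.argsort(D, axis=1, kind="stable")
            sl = y_tr[order]
            sd = np.take_along_axis(D, order, axis=1)
            for k in K_RANGE:
                for wg in WEIGHTINGS:
                    preds[(k, metric, wg)][test_idx] = _predict_sorted(
                        sl, sd, k, wg, classes
                    )
    return [
        Outcome(
            predictions=preds[(c.k, c.distance, c.weighting)],
            accuracy=accuracy(preds[(c.k, c.distance, c.weighting)], y),
            provenance=f"param:{c}",
        )
        for c in grid
    ]


def _mode_vote(pred_matrix: np.ndarray, classes: tuple[int, int]) -> np.ndarray:
    """Elementwise mode over voters (rows); ties resolve to the lower label."""
    lo, hi = classes
    votes_lo = (pred_matrix == lo).sum(axis=0)
    votes_hi = (pred_matrix == hi).sum(axis=0)
    return np.where(votes_lo >= votes_hi, lo, hi)


def imv(outcomes: Sequence[Outcome], labels: np.ndarray) -> list[Outcome]:
    """Iterative majority voting: m outcomes in, m - 2 voted outcomes out.

    Outcomes are sorted by accuracy descending (ties keep original order);
    voted outcome r is the elementwise mode of the top r + 2 prediction
    vectors, r = 1 .. m - 2.
    """
    if len(outcomes) < 3:
        raise ValueError("IMV requires at least three outcomes")
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    classes = (int(classes[0]), int(classes[1]))
    accs = np.array([o.accuracy for o in outcomes])
    order = np.argsort(-accs, kind="stable")
    stacked = np.vstack([outcomes[i].predictions for i in order])
    voted: list[Outcome] = []
    for r in range(1, len(outcomes) - 1):
        pred = _mode_vote(stacked[: r + 2], classes)
        voted.append(
            Outcome(predictions=pred, accuracy=accuracy(pred, y), provenance=f"voted:r={r}")
        )
    return voted


def greedy_best(outcomes: Sequence[Outcome]) -> Outcome:
    """The most accurate outcome; accuracy ties resolve to the earliest."""
    if not outcomes:
        raise ValueError("cannot select from an empty outcome list")
    best = max(range(len(outcomes)), key=lambda i: (outcomes[i].accuracy, -i))
    return outcomes[best]


def tknn(
    features: np.ndarray,
    labels: np.ndarray,
    folds: FoldPlan,
    manifest: DatasetManifest,
    return_candidates: bool = False,
) -> Outcome | tuple[Outcome, list[Outcome]]:
    """Best of the 118 candidates (60 parameter-based + 58 voted) for one
    feature matrix."""
    pots = parameter_outcomes(features, labels, folds, manifest)
    candidates = pots + imv(pots, labels)
    best = greedy_best(candidates)
    if return_candidates:
        return best, candidates
    return best


def fuse(
    tknn_outcomes: Sequence[Outcome],
    labels: np.ndarray,
    return_candidates: bool = False,
) -> Outcome | tuple[Outcome, list[Outcome]]:
    """IMV over the per-feature-vector outcomes, then greedy over the voted set.

    With the usual 15 inputs this produces 13 voted candidates; selection is
    among voted outcomes only.
    """
    voted = imv(tknn_outcomes, labels)
    best = greedy_best(voted)
    best = Outcome(predictions=best.predictions, accuracy=best.accuracy,
                   provenance=f"fused({best.provenance})")
    if return_candidates:
        return best, voted
    return best
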