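"""tkNN grid, IMV voting and greedy outcome selection."""

import numpy as np
import pandas as pd
import pytest

import chminmaxpat as cm
from chminmaxpat.classify import Outcome, _mode_vote

from .reference import naive_mode_votes


def _manifest(n, labels, segments_per_record=1):
    rows = []
    for i in range(n):
        rec = f"r{i // segments_per_record}"
        rows.append(
            {
                "segment_path": f"{i}.csv", "segment_id": f"seg{i}",
                "record_id": rec, "subject_id": rec, "class_label": int(labels[i]),
            }
        )
    return cm.DatasetManifest(rows=pd.DataFrame(rows), class_names={})


def _resub_folds(manifest):
    """Two folds over clustered data so every training part keeps both classes."""
    return cm.make_folds(manifest, "kfold", n_folds=2, seed=0)


def test_grid_enumerates_sixty_configs():
    grid = cm.knn_grid()
    assert len(grid) == 60
    assert len(set(grid)) == 60
    ks = {c.k for c in grid}
    assert ks == set(range(1, 11))


@pytest.mark.parametrize("bad", [dict(k=0), dict(k=11), dict(distance="hamming"),
                                 dict(weighting="uniform")])
def test_config_validation(bad):
    kwargs = dict(k=1, distance="euclidean", weighting="equal") | bad
    with pytest.raises(ValueError):
        cm.KnnConfig(**kwargs)


class TestKnnPredict:
    def test_zero_distance_wins_any_metric(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(10, 3))
        y = np.array([1] * 5 + [2] * 5)
        for metric in cm.DISTANCES:
            cfg = cm.KnnConfig(k=1, distance=metric, weighting="equal")
            pred = cm.knn_predict(train, y, train[[7]], cfg)
            assert pred[0] == 2

    def test_resubstitution_perfect(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        y = rng.permutation([1] * 6 + [2] * 6)
        cfg = cm.KnnConfig(k=1, distance="euclidean", weighting="equal")
        assert cm.accuracy(cm.knn_predict(X, y, X, cfg), y) == 1.0

    def test_inverse_weighting_arithmetic(self):
        train = np.array([[0.0], [10.0]])
        y = np.array([1, 2])
        cfg = cm.KnnConfig(k=2, distance="euclidean", weighting="inverse")
        pred = cm.knn_predict(train, y, np.array([[4.0]]), cfg)
        assert pred[0] == 1  # 1/4 > 1/6

    def test_equal_weighting_tie_goes_to_nearest(self):
        train = np.array([[0.0], [3.0]])
        y = np.array([1, 2])
        cfg = cm.KnnConfig(k=2, distance="cityblock", weighting="equal")
        assert cm.knn_predict(train, y, np.array([[1.0]]), cfg)[0] == 1
        assert cm.knn_predict(train, y, np.array([[2.5]]), cfg)[0] == 2

    def test_cosine_zero_vector_distance_one(self):
        train = np.array([[1.0, 0.0], [0.0, 0.0]])
        y = np.array([1, 2])
        cfg = cm.KnnConfig(k=1, distance="cosine", weighting="equal")
        # zero test vector is at distance 1 from everything; tie -> lower index
        assert cm.knn_predict(train, y, np.array([[0.0, 0.0]]), cfg)[0] == 1

    def test_k_exceeds_training(self):
        cfg = cm.KnnConfig(k=5, distance="euclidean", weighting="equal")
        with pytest.raises(ValueError, match="exceeds"):
            cm.knn_predict(np.ones((3, 1)), np.array([1, 1, 2]), np.ones((1, 1)), cfg)

    def test_agrees_with_sklearn_on_unambiguous_data(self):
        """Independent oracle: scikit-learn kNN, equal weighting, odd k."""
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(2)
        train = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, size=60)
        test = rng.normal(size=(25, 5))
        for k in (1, 3, 7):
            for metric in ("euclidean", "cityblock"):
                cfg = cm.KnnConfig(k=k, distance=metric, weighting="equal")
                ref = KNeighborsClassifier(
                    n_neighbors=k, metric="manhattan" if metric == "cityblock" else metric
                ).fit(train, y)
                np.testing.assert_array_equal(
                    cm.knn_predict(train, y, test, cfg), ref.predict(test)
                )


class TestParameterOutcomes:
    def test_sixty_outcomes_perfectly_separated(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal([5, 0], 0.1, (20, 2)), rng.normal([0, 5], 0.1, (20, 2))]
        )
        labels = np.array([0] * 20 + [1] * 20)
        man = _manifest(40, labels)
        outs = cm.parameter_outcomes(X, labels, _resub_folds(man), man)
        assert len(outs) == 60
        assert all(o.accuracy == 1.0 for o in outs)
        assert all(len(o.predictions) == 40 for o in outs)

    def test_fold_missing_class_is_an_error(self):
        labels = np.array([0, 0, 1, 1])
        man = _manifest(4, labels)
        plan = cm.FoldPlan(
            scheme="kfold",
            assignments={"seg0": 0, "seg1": 0, "seg2": 1, "seg3": 1},
            n_folds=2,
        )
        with pytest.raises(ValueError, match="lacks"):
            cm.parameter_outcomes(np.ones((4, 2)), labels, plan, man)


def _outcomes_from_matrix(preds, labels):
    return [
        Outcome(predictions=p, accuracy=cm.accuracy(p, labels), provenance=f"o{i}")
        for i, p in enumerate(preds)
    ]


class TestImv:
    def test_counts(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=30)
        for m, expected in ((60, 58), (15, 13), (3, 1)):
            preds = rng.integers(0, 2, size=(m, 30))
            voted = cm.imv(_outcomes_from_matrix(preds, labels), labels)
            assert len(voted) == expected

    def test_identical_voters_reproduce_themselves(self):
        labels = np.array([0, 1, 0, 1])
        p = np.array([1, 1, 0, 0])
        voted = cm.imv(_outcomes_from_matrix([p, p, p], labels), labels)
        np.testing.assert_array_equal(voted[0].predictions, p)

    def test_requires_three(self):
        labels = np.array([0, 1])
        with pytest.raises(ValueError, match="three"):
            cm.imv(_outcomes_from_matrix([labels, labels], labels), labels)

    def test_mode_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        preds = rng.choice([3, 9], size=(7, 1000))
        np.testing.assert_array_equal(
            _mode_vote(preds, (3, 9)), naive_mode_votes(preds, 3, 9)
        )

    def test_sorted_by_accuracy_before_voting(self):
        labels = np.zeros(9, dtype=int)
        labels[:3] = 1
        good = labels.copy()
        bad = 1 - labels
        mid = labels.copy()
        mid[0] = 0
        # accuracy order: good (1.0), mid, bad; top-3 vote = mode(good, mid, bad)
        voted = cm.imv(_outcomes_from_matrix([bad, mid, good], labels), labels)
        expected = naive_mode_votes(np.vstack([good, mid, bad]), 0, 1)
        np.testing.assert_array_equal(voted[0].predictions, expected)


class TestGreedyAndTknn:
    def test_tie_prefers_earliest(self):
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1, 0, 1])
        preds = [labels.copy(), labels.copy(), 1 - labels]
        preds[0][0] = 1 - preds[0][0]  # acc 0.9
        outs = _outcomes_from_matrix([preds[0], preds[1], preds[1]], labels)
        best = cm.greedy_best(outs)
        assert best.provenance == "o1"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cm.greedy_best([])

    def test_tknn_dominates_single_parameters_and_is_deterministic(self, tiny_segments):
        mats, _ = cm.extract_features(tiny_segments)
        labels = np.array([s.class_label for s in tiny_segments])
        man = _manifest(len(labels), labels, segments_per_record=2)
        folds = cm.make_folds(man, "kfold", n_folds=4, seed=0)
        X = mats[13]
        best, cands = cm.tknn(X, labels, folds, man, return_candidates=True)
        assert len(cands) == 118
        pot_max = max(c.accuracy for c in cands[:60])
        assert best.accuracy >= pot_max
        best2 = cm.tknn(X, labels, folds, man)
        np.testing.assert_array_equal(best.predictions, best2.predictions)


class TestFuse:
    def test_thirteen_candidates_from_fifteen(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, size=40)
        preds = rng.integers(0, 2, size=(15, 40))
        fused, cands = cm.fuse(_outcomes_from_matrix(preds, labels), labels,
                               return_candidates=True)
        assert len(cands) == 13
        assert fused.accuracy >= min(c.accuracy for c in cands)

    def test_identical_outcomes_pass_through(self):
        labels = np.array([0, 1, 1, 0])
        p = np.array([0, 1, 0, 0])
        outs = _outcomes_from_matrix([p] * 15, labels)
        fused = cm.fuse(outs, labels)
        np.testing.assert_array_equal(fused.predictions, p)
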