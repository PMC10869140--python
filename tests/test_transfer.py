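"""Label/coordinate transfer, k tuning, and the three-fold validation."""

import numpy as np
import pandas as pd
import pytest

from slomap import (
    KNNCoordinateTransfer,
    KNNLabelTransfer,
    SimulationConfig,
    TransferResult,
    integrate_joint,
    simulate_multimodal,
    transfer_coordinates,
    transfer_labels,
    tune_k,
    validate_transfer,
)
from slomap.neighbors import cross_knn


def _brute_force_vote(X_ref, y_ref, X_query, k):
    """Independent oracle: all-pairs distances + explicit plurality vote."""
    from scipy.spatial.distance import cdist

    D = cdist(X_query, X_ref)
    labels, confs = [], []
    for i in range(X_query.shape[0]):
        order = np.argsort(D[i], kind="stable")[:k]
        votes = {}
        for j in order:
            votes.setdefault(y_ref[j], []).append(D[i, j])
        top = max(len(v) for v in votes.values())
        tied = sorted(
            [lab for lab, v in votes.items() if len(v) == top],
            key=lambda lab: (sum(votes[lab]), str(lab)),
        )
        labels.append(tied[0])
        confs.append(top / k)
    return np.array(labels), np.array(confs)


class TestLabelTransfer:
    def test_matches_brute_force_oracle(self, rng):
        X_ref = rng.standard_normal((400, 6))
        y_ref = rng.integers(0, 4, 400).astype(str)
        X_query = rng.standard_normal((100, 6))
        pred, conf = transfer_labels(X_ref, y_ref, X_query, k=7)
        exp_pred, exp_conf = _brute_force_vote(X_ref, y_ref, X_query, 7)
        assert np.array_equal(pred, exp_pred)
        assert np.array_equal(conf, exp_conf)

    def test_unanimous_neighbors_give_full_confidence(self, rng):
        X_ref = np.vstack([rng.standard_normal((20, 3)),
                           rng.standard_normal((20, 3)) + 50])
        y_ref = np.repeat(["A", "B"], 20)
        pred, conf = transfer_labels(X_ref, y_ref, np.array([[50.0, 50, 50]]), k=5)
        assert pred[0] == "B" and conf[0] == 1.0

    def test_three_two_vote(self):
        X_ref = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        y_ref = np.array(["A", "A", "A", "B", "B"])
        pred, conf = transfer_labels(X_ref, y_ref, np.array([[0.0]]), k=5)
        assert pred[0] == "A" and conf[0] == pytest.approx(0.6)

    def test_tie_broken_by_summed_distance(self):
        # 2 votes A (far), 2 votes B (near), 1 vote C: B wins, confidence 0.4
        X_ref = np.array([[3.0], [-3.0], [1.0], [-1.0], [6.0]])
        y_ref = np.array(["A", "A", "B", "B", "C"])
        pred, conf = transfer_labels(X_ref, y_ref, np.array([[0.0]]), k=5)
        assert pred[0] == "B" and conf[0] == pytest.approx(0.4)

    def test_confidence_k_quantized(self, rng):
        X_ref = rng.standard_normal((50, 2))
        y_ref = rng.integers(0, 3, 50).astype(str)
        _, conf = transfer_labels(X_ref, y_ref, rng.standard_normal((30, 2)), k=5)
        assert np.allclose(conf * 5, np.round(conf * 5))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            KNNLabelTransfer(k=1).fit(np.empty((0, 2)), np.array([]))


class TestCoordinateTransfer:
    def test_hand_mean(self):
        X_ref = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        layout = np.array([[0.0, 0], [2, 0], [1, 3], [1, 1], [1, 1]])
        out = transfer_coordinates(X_ref, layout, np.array([[2.0]]), k=5)
        assert np.allclose(out[0], [1.0, 1.0])

    def test_coincident_neighbors(self):
        X_ref = np.zeros((5, 2))
        layout = np.tile([3.0, -2.0], (5, 1))
        out = transfer_coordinates(X_ref, layout, np.array([[0.0, 0.0]]), k=5)
        assert np.allclose(out[0], [3.0, -2.0])

    def test_equals_neighbor_mean_oracle_exactly(self, rng):
        X_ref = rng.standard_normal((200, 4))
        layout = rng.standard_normal((200, 2))
        X_query = rng.standard_normal((60, 4))
        out = transfer_coordinates(X_ref, layout, X_query, k=5)
        idx, _ = cross_knn(X_query, X_ref, 5)
        assert np.array_equal(out, layout[idx].mean(axis=1))

    def test_inside_convex_hull(self, rng):
        X_ref = rng.standard_normal((100, 3))
        layout = rng.standard_normal((100, 2))
        X_query = rng.standard_normal((20, 3))
        out = transfer_coordinates(X_ref, layout, X_query, k=5)
        idx, _ = cross_knn(X_query, X_ref, 5)
        for i in range(20):
            pts = layout[idx[i]]
            assert np.all(out[i] >= pts.min(axis=0) - 1e-12)
            assert np.all(out[i] <= pts.max(axis=0) + 1e-12)


class TestTuneK:
    def test_separated_clusters_pick_smallest_candidate(self, rng):
        X = np.vstack([rng.standard_normal((60, 3)),
                       rng.standard_normal((60, 3)) + 100])
        y = np.repeat(["A", "B"], 60)
        report = tune_k(X, y, [1, 5, 15], seed=0)
        assert report.accuracies == (1.0, 1.0, 1.0)
        assert report.chosen_k == 1

    def test_overlapping_gaussians_averaging_helps(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((300, 2)),
                       rng.standard_normal((300, 2)) + 1.0])
        y = np.repeat(["A", "B"], 300)
        report = tune_k(X, y, [1, 25], seed=0)
        acc = dict(zip(report.candidates, report.accuracies))
        assert acc[25] >= acc[1]
        # oracle cross-check of the hold-out accuracy for k=25
        from sklearn.model_selection import train_test_split

        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=0.7, stratify=y, random_state=0
        )
        exp_pred, _ = _brute_force_vote(X_tr, y_tr, X_te, 25)
        assert acc[25] == pytest.approx(np.mean(exp_pred == y_te))

    def test_same_seed_identical_report(self, rng):
        X = rng.standard_normal((100, 3))
        y = rng.integers(0, 2, 100).astype(str)
        assert tune_k(X, y, [1, 3, 5], seed=4) == tune_k(X, y, [1, 3, 5], seed=4)

    def test_rare_label_excluded_with_warning(self, rng):
        X = rng.standard_normal((41, 2))
        y = np.array(["A"] * 20 + ["B"] * 20 + ["rare"])
        with pytest.warns(UserWarning, match="rare"):
            report = tune_k(X, y, [1], seed=0)
        assert report.chosen_k == 1

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_k(rng.standard_normal((10, 2)), np.zeros(10), [], seed=0)


class TestEndToEnd:
    def test_accuracy_and_confidence_at_three_sigma(self):
        """Pooled over seeds 0-4 at 3-sigma separation: accuracy >= 0.95,
        and mean annotation confidence >= 0.9 on every seed."""
        correct = total = 0
        for seed in range(5):
            ref, query, truth = simulate_multimodal(SimulationConfig(seed=seed))
            emb = integrate_joint(ref, query)
            is_ref = emb.origin == "reference"
            y = truth.table.set_index("cell_id").loc[emb.cell_ids, "label"].to_numpy()
            pred, conf = transfer_labels(emb.coords[is_ref], y[is_ref], emb.coords[~is_ref], k=5)
            correct += int(np.sum(pred == y[~is_ref]))
            total += int((~is_ref).sum())
            assert conf.mean() >= 0.9
        assert correct / total >= 0.95

    def test_accuracy_degrades_toward_chance_as_separation_shrinks(self):
        accs = {}
        for sep in (3.0, 1.5, 0.0):
            ref, query, truth = simulate_multimodal(SimulationConfig(seed=0, separation=sep))
            emb = integrate_joint(ref, query)
            is_ref = emb.origin == "reference"
            y = truth.table.set_index("cell_id").loc[emb.cell_ids, "label"].to_numpy()
            pred, _ = transfer_labels(emb.coords[is_ref], y[is_ref], emb.coords[~is_ref], k=5)
            accs[sep] = np.mean(pred == y[~is_ref])
        assert accs[3.0] > accs[1.5] > accs[0.0]
        assert abs(accs[0.0] - 1 / 3) < 0.1  # chance for 3 balanced labels


class TestValidateTransfer:
    @staticmethod
    def _setup(seed=0, permute=False):
        ref, query, truth = simulate_multimodal(SimulationConfig(seed=seed))
        emb = integrate_joint(ref, query)
        is_ref = emb.origin == "reference"
        y = truth.table.set_index("cell_id").loc[emb.cell_ids, "label"].to_numpy()
        y_ref = y[is_ref].copy()
        if permute:
            y_ref = np.random.default_rng(seed).permutation(y_ref)
        pred, conf = transfer_labels(emb.coords[is_ref], y_ref, emb.coords[~is_ref], k=5)
        return emb, is_ref, y_ref, pred, conf, ref, query

    def test_self_transfer_marker_conservation_is_one(self, multimodal):
        from slomap.integration import lognormalize

        reference, _, _ = multimodal
        expr = lognormalize(reference[0].layers["counts"])
        genes = list(reference[0].var_names)
        y = reference[0].obs["label"].to_numpy()
        rng = np.random.default_rng(0)
        X = rng.standard_normal((len(y), 5))
        markers = {lab: genes[:10] for lab in np.unique(y)}
        result = TransferResult(
            cell_ids=list(reference[0].obs_names), labels=y.copy(),
            confidence=np.ones(len(y)), k=5,
        )
        report = validate_transfer(X, y, expr, X, expr, genes, result, markers, k=5)
        assert np.allclose(report["marker_conservation"], 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_well_separated_confidence_high(self, seed):
        emb, is_ref, y_ref, pred, conf, ref, query = self._setup(seed)
        from slomap.integration import lognormalize

        genes = list(ref[0].var_names)
        markers = {lab: genes[:5] for lab in np.unique(y_ref)}
        result = TransferResult(
            cell_ids=[c for c, r in zip(emb.cell_ids, is_ref) if not r],
            labels=pred, confidence=conf, k=5,
        )
        report = validate_transfer(
            emb.coords[is_ref], y_ref, lognormalize(ref[0].layers["counts"]),
            emb.coords[~is_ref], lognormalize(query[0].layers["counts"]),
            genes, result, markers, k=5,
        )
        assert (report["confidence_mean"].dropna() >= 0.9).all()
        assert (report["neighborhood_preservation"].dropna() >= 0.85).all()

    def test_permuted_labels_drop_confidence_to_chance(self):
        emb, is_ref, y_ref, pred, conf, *_ = self._setup(0, permute=True)
        # with 3 balanced labels the plurality fraction of 5 random votes
        # has expectation ~0.50; well below the separated-cluster regime
        assert conf.mean() < 0.65
        assert conf.mean() > 0.35
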