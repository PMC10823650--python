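"""Fold construction and ranking metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circlink import aupr, auroc, build_association_matrix, make_folds


def brute_force_auroc(scores, labels):
    """Concordant pos-neg pair counting with half-credit ties: O(P*N)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_sweep_aupr(scores, labels):
    """Step-interpolated PR area by enumerating every distinct threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestMakeFolds:
    def test_even_split(self):
        A = build_association_matrix([(f"c{i}", f"d{i % 3}") for i in range(10)])
        split = make_folds(A, n_folds=5, seed=1)
        sizes = np.bincount(split.fold_id, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_partition_contract(self):
        A = build_association_matrix([(f"c{i}", f"d{i % 4}") for i in range(13)])
        split = make_folds(A, n_folds=5, seed=2)
        all_cells = np.concatenate([split.test_cells(f) for f in range(5)])
        assert len(all_cells) == 13
        assert len({tuple(c) for c in all_cells}) == 13
        assert np.ptp(np.bincount(split.fold_id)) <= 1

    def test_deterministic(self):
        A = build_association_matrix([(f"c{i}", "d0") for i in range(9)])
        s1 = make_folds(A, n_folds=3, seed=7)
        s2 = make_folds(A, n_folds=3, seed=7)
        np.testing.assert_array_equal(s1.fold_id, s2.fold_id)

    def test_too_few_positives(self):
        A = build_association_matrix([("c1", "d1"), ("c2", "d2")])
        with pytest.raises(ValueError, match="too few"):
            make_folds(A, n_folds=5)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_interleaved_example(self):
        # 3 of 4 pos-neg pairs concordant
        assert auroc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 200)
            scores = rng.choice(np.round(rng.random(20), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    @given(
        st.lists(st.floats(-5, 5), min_size=4, max_size=40),
        st.floats(0.1, 3.0),
    )
    def test_invariant_under_monotone_transform(self, raw, slope):
        # round so the transform cannot collapse distinct scores into float ties
        scores = np.round(np.array(raw), 3)
        labels = (np.arange(len(scores)) % 2).astype(int)
        transformed = np.exp(slope * scores)
        assert auroc(scores, labels) == pytest.approx(auroc(transformed, labels))


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_tied_equals_prevalence(self):
        scores = [0.5] * 10
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        assert aupr(scores, labels) == pytest.approx(0.3)
        assert threshold_sweep_aupr(scores, labels) == pytest.approx(0.3)

    def test_interleaved_example_matches_sweep(self):
        scores, labels = [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        assert aupr(scores, labels) == pytest.approx(
            threshold_sweep_aupr(scores, labels), abs=1e-12
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            aupr([0.5, 0.6], [0, 0])

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(5, 200)
            scores = rng.choice(np.round(rng.random(15), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            assert aupr(scores, labels) == pytest.approx(
                threshold_sweep_aupr(scores, labels), abs=1e-12
            )


class TestCrossValidate:
    def test_report_on_tiny_fixture(self, tiny_bundle, fast_cfg):
        from circlink import cross_validate

        report = cross_validate(
            tiny_bundle.A_full,
            tiny_bundle.side_nets,
            fast_cfg,
            n_folds=3,
            seed=11,
            mf_k=8,
        )
        assert len(report.auroc_folds) == 3
        assert ((report.auroc_folds >= 0) & (report.auroc_folds <= 1)).all()
        assert ((report.aupr_folds >= 0) & (report.aupr_folds <= 1)).all()
        # planted structure is learnable even at this small size
        assert report.auroc > 0.6

    def test_random_scores_are_chance_level(self, tiny_bundle, rng):
        from circlink.evaluation import masked_recovery_metrics

        A_full = np.asarray(tiny_bundle.A_full.values, float)
        A_train = np.asarray(tiny_bundle.A_train.values, float)
        rocs = [
            masked_recovery_metrics(rng.random(A_full.shape), A_full, A_train)[0]
            for _ in range(20)
        ]
        assert np.mean(rocs) == pytest.approx(0.5, abs=0.05)
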