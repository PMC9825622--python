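"""Activity binning, ordinal encoding/decision, oversampling, folds,
classifier training and the voting ensemble."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlm.chem_io import ActivityClass
from chemlm.errors import (DegenerateClass, DegenerateTestSet,
                           TooFewRecords)
from chemlm.ordinal import (ClassifierSpec, OrdinalClassifier, assign_class,
                            clustered_folds, decide, decode_ordinal,
                            encode_ordinal, ensemble_votes, fpr_at_tpr,
                            oversample, rank_library, roc_operating_point)

I, M, H = (ActivityClass.INACTIVE, ActivityClass.MODERATELY_ACTIVE,
           ActivityClass.HIGHLY_ACTIVE)


class TestBinning:
    @pytest.mark.parametrize("pic50,expected", [
        (4.0, I),       # boundary belongs to the lower class
        (6.5, M),       # boundary belongs to the lower class
        (7.2, H),
        (3.0, I),
        (5.0, M),
        (4.000001, M),
    ])
    def test_partition(self, pic50, expected):
        assert assign_class(pic50) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            assign_class(float("nan"))


class TestOrdinalEncoding:
    @pytest.mark.parametrize("cls,target", [
        (I, [1, 0, 0]), (M, [1, 1, 0]), (H, [1, 1, 1])])
    def test_cumulative_coding(self, cls, target):
        np.testing.assert_array_equal(encode_ordinal(cls), target)

    @pytest.mark.parametrize("cls", list(ActivityClass))
    @pytest.mark.parametrize("encoding", ["cumulative", "onehot"])
    def test_round_trip(self, cls, encoding):
        assert decode_ordinal(encode_ordinal(cls, encoding), encoding) == cls


class TestDecide:
    @pytest.mark.parametrize("outputs,expected", [
        ((0.9, 0.8, 0.7), H),       # all pass the 0.4 threshold
        ((0.9, 0.3, 0.9), I),       # scan stops at the second output
        ((0.0, 0.0, 0.0), I),
        ((0.9, 0.8, 0.1), M),
        ((0.4, 0.9, 0.9), I),       # strict '>' at the threshold
    ])
    def test_scan_rule(self, outputs, expected):
        assert decide(np.array(outputs)) == expected

    @given(st.tuples(*[st.floats(0, 1)] * 3),
           st.tuples(*[st.floats(0, 1)] * 3))
    @settings(max_examples=300, deadline=None)
    def test_monotone_in_outputs(self, a, b):
        """Element-wise larger outputs never yield a lower class."""
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        assert decide(hi) >= decide(lo)

    def test_onehot_mode_uses_third_unit(self):
        assert decide(np.array([0.9, 0.9, 0.5]),
                      encoding="onehot") == H
        assert decide(np.array([0.9, 0.9, 0.3]),
                      encoding="onehot") == M


def make_labeled(sizes):
    out = []
    for cls, n in zip(ActivityClass, sizes):
        out += [([1, 3, 2], cls)] * n
    return out


class TestOversample:
    def test_published_class_sizes(self):
        """(34, 121, 43) gains +40 on the two smaller classes."""
        data = oversample(make_labeled((34, 121, 43)), add=40, seed=0)
        counts = {c: sum(1 for _, cc in data if cc == c)
                  for c in ActivityClass}
        assert (counts[I], counts[M], counts[H]) == (74, 121, 83)
        assert len(data) == 34 + 121 + 43 + 80

    def test_tie_broken_toward_lower_classes(self):
        data = oversample(make_labeled((5, 5, 5)), add=40, seed=0)
        counts = {c: sum(1 for _, cc in data if cc == c)
                  for c in ActivityClass}
        assert (counts[I], counts[M], counts[H]) == (45, 45, 5)

    def test_add_zero_is_identity(self):
        base = make_labeled((3, 4, 5))
        assert oversample(base, add=0, seed=1) == base

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateClass):
            oversample(make_labeled((0, 4, 5)), add=10)

    def test_draws_are_seeded(self):
        base = make_labeled((4, 9, 5))
        assert oversample(base, add=7, seed=3) == oversample(
            base, add=7, seed=3)


class TestClusteredFolds:
    def _blobs(self, rng, k=5, per=12, n_bits=64):
        centers = (rng.random((k, n_bits)) < 0.5)
        rows, truth = [], []
        for c in range(k):
            for _ in range(per):
                row = centers[c].copy()
                flip = rng.integers(0, n_bits, size=2)
                row[flip] = ~row[flip]
                rows.append(row)
                truth.append(c)
        return np.array(rows, dtype=float), np.array(truth)

    def test_planted_blobs_recovered(self, rng):
        X, truth = self._blobs(rng)
        folds = clustered_folds(X, k=5, seed=0)
        # cluster labels must be a relabelling of the planted partition
        for c in range(5):
            members = folds.labels[truth == c]
            assert len(set(members)) == 1
        assert len(set(folds.labels)) == 5

    def test_k1_rejected(self, rng):
        X, _ = self._blobs(rng)
        with pytest.raises(ValueError):
            clustered_folds(X, k=1)

    def test_too_few_records(self):
        with pytest.raises(TooFewRecords):
            clustered_folds(np.zeros((3, 8)), k=5)

    def test_seeded_determinism(self, rng):
        X, _ = self._blobs(rng)
        a = clustered_folds(X, k=5, seed=9)
        b = clustered_folds(X, k=5, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_test_cluster_partition(self, rng):
        X, _ = self._blobs(rng)
        folds = clustered_folds(X, k=5, seed=0)
        assert set(folds.test_indices) | set(folds.cv_indices) \
            == set(range(len(X)))
        assert not set(folds.test_indices) & set(folds.cv_indices)


class FixedModel:
    """Stub with a fixed decision, for vote arithmetic."""

    def __init__(self, cls):
        self.cls = cls

    def predict_class(self, seqs):
        return [self.cls] * len(seqs)


class TestEnsembleVotes:
    def test_unanimous(self):
        models = [FixedModel(H)] * 10
        assert ensemble_votes(models, [[1, 2]]).tolist() == [10]

    def test_none_pass(self):
        models = [FixedModel(M)] * 10
        assert ensemble_votes(models, [[1, 2]]).tolist() == [0]

    def test_seven_of_ten(self):
        models = [FixedModel(H)] * 7 + [FixedModel(I)] * 3
        assert ensemble_votes(models, [[1, 2]]).tolist() == [7]

    def test_permutation_invariance(self, rng):
        models = [FixedModel(H if rng.random() < 0.5 else M)
                  for _ in range(12)]
        seqs = [[1, 2], [1, 3]]
        base = ensemble_votes(models, seqs)
        for _ in range(5):
            perm = list(rng.permutation(len(models)))
            np.testing.assert_array_equal(
                ensemble_votes([models[i] for i in perm], seqs), base)


class TestRankLibrary:
    votes = np.array([3, 9, 0, 10, 9])

    def test_confidence_zero_returns_all(self):
        assert len(rank_library(self.votes, 0)) == 5

    def test_confidence_above_max_empty(self):
        assert rank_library(self.votes, 11) == []

    def test_vote_order_with_stable_ties(self):
        top = rank_library(self.votes, 9)
        assert [(p.index, p.votes) for p in top] == [(3, 10), (1, 9), (4, 9)]

    def test_counts_nonincreasing_in_confidence(self, rng):
        votes = rng.integers(0, 11, size=50)
        counts = [len(rank_library(votes, c)) for c in range(12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRocOperatingPoint:
    def test_perfect_classifier(self):
        truth = [H] * 4 + [I] * 4
        assert roc_operating_point(truth, truth) == (100.0, 0.0)

    def test_constant_high_classifier(self):
        truth = [H] * 4 + [I] * 4
        assert roc_operating_point([H] * 8, truth) == (100.0, 100.0)

    def test_hand_built_confusion(self):
        # 4 TP, 1 FN among 5 high; 2 FP, 3 TN among 5 inactive
        truth = [H] * 5 + [I] * 5
        pred = [H, H, H, H, M] + [H, H, I, I, I]
        assert roc_operating_point(pred, truth) == (80.0, 40.0)

    def test_degenerate_test_set_rejected(self):
        with pytest.raises(DegenerateTestSet):
            roc_operating_point([H, H], [H, H])

    def test_fpr_at_tpr_scans_cutoffs(self):
        truth = [H, H, H, I, I, I]
        votes = np.array([9, 8, 2, 3, 1, 0])
        # cutoff 8 reaches TPR 66.7 (FPR 0); cutoff 2 reaches 100 (FPR 33.3)
        assert fpr_at_tpr(votes, truth, 100.0) == pytest.approx(100 / 3)
        assert fpr_at_tpr(votes, truth, 60.0) == 0.0


@pytest.fixture(scope="module")
def trained(vocab, labeled_activity, trained_eclm):
    spec = ClassifierSpec(len(vocab), h1=64, h2=16, epochs=40,
                          oversample_add=20)
    clf = OrdinalClassifier(vocab, spec, seed=5)
    clf.load_backbone(trained_eclm)
    data = oversample(labeled_activity[:110], add=20, seed=5)
    clf.fit(data, seed=5)
    return clf


class TestClassifierTraining:

    def test_beats_majority_baseline(self, trained, labeled_activity):
        train = labeled_activity[:110]
        pred = trained.predict_class([s for s, _ in train])
        acc = np.mean([p == c for p, (_, c) in zip(pred, train)])
        counts = {c: sum(1 for _, cc in train if cc == c)
                  for c in ActivityClass}
        majority = max(counts.values()) / len(train)
        assert acc > majority

    def test_separates_planted_signal(self, trained, labeled_activity):
        """Held-out AUC for the highly-active output exceeds 0.9."""
        from sklearn.metrics import roc_auc_score
        held = labeled_activity[110:]
        outs = trained.predict_outputs([s for s, _ in held])
        y = [int(c == H) for _, c in held]
        assert roc_auc_score(y, outs[:, 2]) > 0.9

    def test_freeze_both_blocks_keeps_backbone_bit_identical(
            self, vocab, labeled_activity, trained_eclm):
        spec = ClassifierSpec(len(vocab), h1=64, h2=16, epochs=3)
        clf = OrdinalClassifier(vocab, spec, seed=2)
        clf.load_backbone(trained_eclm)
        before = {f"{l.name}.{k}": v.copy() for l in clf.backbone.layers
                  for k, v in list(l.params.items()) + list(l.stats.items())}
        clf.fit(labeled_activity[:60], freeze="both-blocks", seed=2)
        for l in clf.backbone.layers:
            for k, v in list(l.params.items()) + list(l.stats.items()):
                np.testing.assert_array_equal(v, before[f"{l.name}.{k}"])

    def test_zero_epochs_leaves_outputs_unchanged(self, vocab,
                                                  labeled_activity):
        spec = ClassifierSpec(len(vocab), h1=16, h2=4, epochs=0)
        clf = OrdinalClassifier(vocab, spec, seed=3)
        probe = [s for s, _ in labeled_activity[:5]]
        before = clf.predict_outputs(probe)
        clf.fit(labeled_activity[:30], seed=3)
        np.testing.assert_array_equal(clf.predict_outputs(probe), before)
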