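"""Ordinal three-class bioactivity classification with deep ensembles.

Activity is binned on pIC50 into three ordered classes — inactive
(pIC50 <= 4.0), moderately active (4.0 < pIC50 <= 6.5) and highly active
(pIC50 > 6.5).  A classifier head (dropout + three sigmoid units) sits on
the shared recurrent backbone, whose weights can be seeded from either an
ELECTRA-pretrained or an autoregressively pretrained model.  Class
imbalance is mitigated by oversampling the two smaller classes; model
selection uses k-means clustered folds on Morgan fingerprints.  Prediction
confidence is the number of ensemble members voting "highly active".

Two output encodings are supported:

* ``cumulative`` (default): Frank–Hall coding, target (1,0,0)/(1,1,0)/
  (1,1,1); the decision scans outputs left to right and stops at the
  first one not exceeding the sigmoid threshold.
* ``onehot``: one unit per class; "highly active" iff the third unit
  exceeds the threshold, otherwise the moderate unit is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .chem_io import ActivityClass, Vocabulary
from .errors import (DegenerateClass, DegenerateTestSet, ShapeMismatch,
                     TooFewRecords, VocabMismatch)

LabeledSeq = tuple[list[int], ActivityClass]


# ---------------------------------------------------------------------------
# Binning and encodings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityBinning:
    """pIC50 cuts partitioning the line into the three ordered classes."""

    low_cut: float = 4.0
    high_cut: float = 6.5


DEFAULT_BINNING = ActivityBinning()


def assign_class(pIC50: float,
                 binning: ActivityBinning = DEFAULT_BINNING) -> ActivityClass:
    """Bin a pIC50 value; boundary values fall in the lower class."""
    if not np.isfinite(pIC50):
        raise ValueError(f"pIC50 must be finite, got {pIC50}")
    if pIC50 <= binning.low_cut:
        return ActivityClass.INACTIVE
    if pIC50 <= binning.high_cut:
        return ActivityClass.MODERATELY_ACTIVE
    return ActivityClass.HIGHLY_ACTIVE


def encode_ordinal(cls: ActivityClass, encoding: str = "cumulative"
                   ) -> np.ndarray:
    """Target vector for the three sigmoid outputs."""
    c = int(cls)
    if encoding == "cumulative":
        return np.array([1.0] * (c + 1) + [0.0] * (2 - c), dtype=np.float64)
    if encoding == "onehot":
        v = np.zeros(3)
        v[c] = 1.0
        return v
    raise ValueError(f"unknown encoding {encoding!r}")


def decode_ordinal(target: np.ndarray, encoding: str = "cumulative"
                   ) -> ActivityClass:
    if encoding == "cumulative":
        return ActivityClass(int(np.sum(target > 0.5)) - 1)
    return ActivityClass(int(np.argmax(target)))


def decide(outputs: np.ndarray, threshold: float = 0.4,
           encoding: str = "cumulative") -> ActivityClass:
    """Map the three sigmoid outputs to a class.

    Cumulative coding: count the leading outputs strictly above the
    threshold; the class is one less than that count, floored at inactive
    (so a sub-threshold first output, or a gap in the scan, is inactive).
    Monotone: raising any output can never lower the class.
    """
    outputs = np.asarray(outputs, dtype=np.float64)
    if encoding == "cumulative":
        leading = 0
        for o in outputs:
            if o > threshold:
                leading += 1
            else:
                break
        return ActivityClass(max(leading - 1, 0))
    if encoding == "onehot":
        if outputs[2] > threshold:
            return ActivityClass.HIGHLY_ACTIVE
        if outputs[1] > threshold:
            return ActivityClass.MODERATELY_ACTIVE
        return ActivityClass.INACTIVE
    raise ValueError(f"unknown encoding {encoding!r}")


# ---------------------------------------------------------------------------
# Oversampling and clustered folds
# ---------------------------------------------------------------------------

def oversample(labeled: list, add: int = 40, seed: int = 0,
               key=None) -> list:
    """Add ``add`` uniform-with-replacement copies to the two smallest classes.

    The largest class is untouched; output size is ``n + 2*add``.  Ties in
    class size are broken toward the lower ordinal class.  ``key`` extracts
    the class label (default: second tuple element).
    """
    key = key or (lambda r: r[1])
    by_class: dict[ActivityClass, list[int]] = {c: [] for c in ActivityClass}
    for i, rec in enumerate(labeled):
        by_class[key(rec)].append(i)
    empties = [c for c, idx in by_class.items() if not idx]
    if empties:
        raise DegenerateClass(f"empty classes: {empties}")
    order = sorted(ActivityClass, key=lambda c: (len(by_class[c]), int(c)))
    minority = order[:2]
    rng = np.random.default_rng(seed)
    out = list(labeled)
    for c in minority:
        pool = by_class[c]
        draws = rng.integers(0, len(pool), size=add)
        out.extend(labeled[pool[int(d)]] for d in draws)
    return out


@dataclass
class FoldAssignment:
    labels: np.ndarray            # cluster index per record
    k: int
    test_cluster: int

    @property
    def test_indices(self) -> np.ndarray:
        return np.nonzero(self.labels == self.test_cluster)[0]

    @property
    def cv_indices(self) -> np.ndarray:
        return np.nonzero(self.labels != self.test_cluster)[0]


def clustered_folds(fingerprints: np.ndarray, k: int = 5, seed: int = 0,
                    test_cluster: int | None = None) -> FoldAssignment:
    """k-means clustering of fingerprint vectors into CV folds + test fold.

    Euclidean distance on 0/1 coordinates (monotone in Hamming distance).
    One cluster (default the last index) is held out for testing; the
    remainder are cross-validation folds.
    """
    fingerprints = np.asarray(fingerprints, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be >= 2: one test cluster plus CV folds")
    if fingerprints.shape[0] < k:
        raise TooFewRecords(
            f"{fingerprints.shape[0]} records for k={k} clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(fingerprints)
    return FoldAssignment(labels=labels, k=k,
                          test_cluster=k - 1 if test_cluster is None
                          else test_cluster)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """Hyperparameters of the ordinal classifier head and training."""

    vocab_size: int
    h1: int = 1024
    h2: int = 256
    dropout: float = 0.2
    lr: float = 1e-4
    epochs: int = 200
    threshold: float = 0.4
    oversample_add: int = 40
    encoding: str = "cumulative"


class OrdinalClassifier:
    """Backbone + dropout + three-sigmoid head, trained with BCE."""

    def __init__(self, vocab: Vocabulary, spec: ClassifierSpec, seed: int = 0):
        if spec.vocab_size != len(vocab):
            raise ShapeMismatch("vocab size mismatch with classifier spec")
        self.vocab = vocab
        self.spec = spec
        rng = nn._rng(seed)
        self.backbone = nn.Backbone(spec.vocab_size, spec.h1, spec.h2, rng)
        self.dropout = nn.Dropout("dropout", spec.dropout, rng)
        self.head = nn.Dense("cls_head", spec.h2, 3, rng)

    @property
    def layers(self) -> list[nn.Layer]:
        return self.backbone.layers + [self.dropout, self.head]

    def n_parameters(self, include_stats: bool = True) -> int:
        return sum(l.n_parameters(include_stats) for l in self.layers)

    def load_backbone(self, source) -> None:
        """Seed the backbone from a pretrained CLM, E-CLM or checkpoint dir."""
        if isinstance(source, (str, Path)):
            _, weights = nn.load_weights(source)
        else:
            if len(source.vocab) != len(self.vocab) or \
                    source.vocab.tokens != self.vocab.tokens:
                raise VocabMismatch("backbone vocabulary differs")
            weights = {}
            for layer in source.backbone.layers:
                weights.update(layer.state_dict())
        for layer in self.backbone.layers:
            layer.load_state_dict(weights)

    # -- forward/backward ---------------------------------------------------
    def _forward(self, seqs: list[list[int]], training: bool) -> np.ndarray:
        pad = self.vocab.pad
        tok = nn.pad_batch(seqs, pad)
        x = nn.one_hot(tok, self.spec.vocab_size)
        feats = self.backbone.forward(x, training)
        self._last_idx = np.array([len(s) - 1 for s in seqs])
        taken = feats[np.arange(len(seqs)), self._last_idx]
        self._feat_shape = feats.shape
        h = self.dropout.forward(taken, training)
        return self.head.forward(h, training)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dropout.backward(d)
        dfeats = np.zeros(self._feat_shape, nn.DTYPE)
        dfeats[np.arange(len(self._last_idx)), self._last_idx] = d
        self.backbone.backward(dfeats)

    FREEZE_PLANS = {
        "none": (),
        "first-block": ("lstm1",),
        "second-block": ("lstm2",),
        "both-blocks": ("bn_in", "lstm1", "lstm2", "bn_out"),
    }

    def fit(self, labeled: list[LabeledSeq], epochs: int | None = None,
            freeze: str = "none", batch_size: int = 32,
            seed: int = 0) -> list[float]:
        """Train on (token sequence, class) pairs; returns loss history."""
        V = self.spec.vocab_size
        for seq, _ in labeled:
            if any(i < 0 or i >= V for i in seq):
                raise VocabMismatch("token index outside classifier vocabulary")
        try:
            frozen_names = self.FREEZE_PLANS[freeze]
        except KeyError:
            raise ValueError(f"unknown freeze plan {freeze!r}") from None
        frozen = [getattr(self.backbone, n) for n in frozen_names]
        for l in frozen:
            l.trainable = False
        bn_frozen = [l for l in frozen if isinstance(l, nn.BatchNorm)]
        for bn in bn_frozen:
            bn.inference_only = True
        epochs = self.spec.epochs if epochs is None else epochs
        rng = nn._rng(seed)
        self.dropout.rng = nn._rng(rng.integers(2 ** 31))
        opt = nn.Adam(self.layers, lr=self.spec.lr)
        targets = np.stack([encode_ordinal(c, self.spec.encoding)
                            for _, c in labeled])
        order = np.arange(len(labeled))
        history: list[float] = []
        try:
            for _ in range(epochs):
                rng.shuffle(order)
                total, nb = 0.0, 0
                for lo in range(0, len(order), batch_size):
                    rows = order[lo:lo + batch_size]
                    seqs = [labeled[i][0] for i in rows]
                    y = targets[rows]
                    logits = self._forward(seqs, training=True)
                    loss, dlogits = nn.masked_binary_cross_entropy(
                        logits, y, np.ones_like(y))
                    self._backward(dlogits)
                    opt.step()
                    total += loss
                    nb += 1
                history.append(total / max(nb, 1))
        finally:
            for l in frozen:
                l.trainable = True
            for bn in bn_frozen:
                bn.inference_only = False
        return history

    def predict_outputs(self, seqs: list[list[int]]) -> np.ndarray:
        """Sigmoid activations of the three output units, shape (n, 3)."""
        logits = self._forward(seqs, training=False)
        return 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))

    def predict_class(self, seqs: list[list[int]]) -> list[ActivityClass]:
        return [decide(o, self.spec.threshold, self.spec.encoding)
                for o in self.predict_outputs(seqs)]

    def save(self, path: str | Path) -> None:
        arch = {"kind": "ordinal", "vocab": self.vocab.tokens,
                "scheme": self.vocab.scheme, "h1": self.spec.h1,
                "h2": self.spec.h2, "encoding": self.spec.encoding,
                "threshold": self.spec.threshold}
        nn.save_checkpoint(path, arch, self.layers)

    @classmethod
    def load(cls, path: str | Path) -> "OrdinalClassifier":
        arch, weights = nn.load_weights(path)
        vocab = Vocabulary(tokens=arch["vocab"],
                           scheme=arch.get("scheme", "token"))
        spec = ClassifierSpec(vocab_size=len(vocab), h1=arch["h1"],
                              h2=arch["h2"],
                              encoding=arch.get("encoding", "cumulative"),
                              threshold=arch.get("threshold", 0.4))
        model = cls(vocab, spec, seed=0)
        for layer in model.layers:
            layer.load_state_dict(weights)
        return model


# ---------------------------------------------------------------------------
# Deep ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsemblePrediction:
    index: int                 # position in the scored library
    smiles: str | None
    votes: int
    M: int


def train_ensemble(vocab: Vocabulary, spec: ClassifierSpec,
                   labeled: list[LabeledSeq], M: int,
                   backbone=None, epochs: int | None = None,
                   base_seed: int = 0) -> list[OrdinalClassifier]:
    """Train ``M`` classifiers differing only in their per-member seed.

    The member seed controls weight initialization, shuffling, dropout and
    the oversampling draws; architecture, data and schedule are shared.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(M) & 0x7FFFFFFF
    members = []
    for s in seeds:
        s = int(s)
        model = OrdinalClassifier(vocab, spec, seed=s)
        if backbone is not None:
            model.load_backbone(backbone)
        data = oversample(labeled, add=spec.oversample_add, seed=s)
        model.fit(data, epochs=epochs, seed=s)
        members.append(model)
    return members


def ensemble_votes(models: list[OrdinalClassifier],
                   seqs: list[list[int]]) -> np.ndarray:
    """Votes per molecule: members deciding "highly active"."""
    votes = np.zeros(len(seqs), dtype=np.int64)
    for m in models:
        pred = m.predict_class(seqs)
        votes += np.array([c == ActivityClass.HIGHLY_ACTIVE for c in pred])
    return votes


def rank_library(votes: np.ndarray, confidence: int,
                 smiles: list[str] | None = None,
                 M: int | None = None) -> list[EnsemblePrediction]:
    """Molecules with at least ``confidence`` votes, best first.

    Sorted by votes descending with input order breaking ties; the size of
    the result is non-increasing in the confidence level.
    """
    votes = np.asarray(votes)
    M = int(votes.max(initial=0)) if M is None else M
    keep = [i for i in range(len(votes)) if votes[i] >= confidence]
    keep.sort(key=lambda i: (-votes[i], i))
    return [EnsemblePrediction(
        index=i, smiles=smiles[i] if smiles is not None else None,
        votes=int(votes[i]), M=M) for i in keep]


def roc_operating_point(pred_classes: list[ActivityClass],
                        true_classes: list[ActivityClass]
                        ) -> tuple[float, float]:
    """(TPR, FPR) in percent for the highly-active vs inactive task."""
    true_classes = list(true_classes)
    pred_classes = list(pred_classes)
    pos = [i for i, c in enumerate(true_classes)
           if c == ActivityClass.HIGHLY_ACTIVE]
    neg = [i for i, c in enumerate(true_classes)
           if c == ActivityClass.INACTIVE]
    if not pos or not neg:
        raise DegenerateTestSet(
            "need both highly-active and inactive molecules")
    high = ActivityClass.HIGHLY_ACTIVE
    tpr = 100.0 * sum(pred_classes[i] == high for i in pos) / len(pos)
    fpr = 100.0 * sum(pred_classes[i] == high for i in neg) / len(neg)
    return tpr, fpr


def fpr_at_tpr(votes: np.ndarray, true_classes: list[ActivityClass],
               tpr_target: float) -> float:
    """Minimal FPR (percent) over vote cutoffs achieving TPR >= target.

    Scans every confidence cutoff of the voting ensemble; returns 100.0 if
    the target sensitivity is unreachable.
    """
    votes = np.asarray(votes)
    pos = np.array([c == ActivityClass.HIGHLY_ACTIVE for c in true_classes])
    neg = np.array([c == ActivityClass.INACTIVE for c in true_classes])
    if not pos.any() or not neg.any():
        raise DegenerateTestSet(
            "need both highly-active and inactive molecules")
    best = 100.0
    for cut in range(0, int(votes.max(initial=0)) + 2):
        pred = votes >= cut
        tpr = 100.0 * (pred & pos).sum() / pos.sum()
        fpr = 100.0 * (pred & neg).sum() / neg.sum()
        if tpr >= tpr_target:
            best = min(best, fpr)
    return best
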