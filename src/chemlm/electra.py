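"""ELECTRA-style pretraining for SMILES: replaced-token detection.

Token sequences are corrupted by independently substituting each chemical
(non-special) position with probability ``rate``, drawing the replacement
uniformly from the other chemical tokens.  A discriminator with the same
recurrent backbone as the generative model is trained with per-position
binary cross-entropy to flag the substituted positions.  Unlike the
original ELECTRA formulation there is no generator network: replacements
are uniform random.  A fresh corruption is drawn every epoch from a
per-epoch derived seed so the model cannot memorize one mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .chem_io import TokenizedString, Vocabulary
from .errors import (InvalidTrainingData, ShapeMismatch,
                     SingletonVocabulary)
from .generative import GenerativeArchitectureSpec


@dataclass
class CorruptionResult:
    corrupted: TokenizedString
    labels: np.ndarray      # 1 exactly where corrupted differs from original
    rate: float
    seed: int


def corrupt(ts: TokenizedString, rate: float, vocab: Vocabulary,
            seed: int) -> CorruptionResult:
    """Randomly substitute chemical tokens, labelling the changed positions.

    Special tokens (pad/start/stop) are never touched.  Each substitution
    draws uniformly from the chemical tokens excluding the original, so a
    labelled position always differs from the original sequence.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    chem = vocab.chemical_indices
    if len(chem) < 2:
        raise SingletonVocabulary("need >= 2 chemical tokens to corrupt")
    rng = np.random.default_rng(seed)
    idx = np.asarray(ts.token_indices, dtype=np.int64)
    labels = np.zeros(len(idx), dtype=np.int64)
    special = vocab.special_indices
    out = idx.copy()
    for pos in range(len(idx)):
        if int(idx[pos]) in special:
            continue
        if rng.random() < rate:
            alternatives = [c for c in chem if c != idx[pos]]
            out[pos] = alternatives[int(rng.integers(len(alternatives)))]
            labels[pos] = 1
    return CorruptionResult(
        corrupted=TokenizedString(token_indices=out.tolist(), length=ts.length),
        labels=labels, rate=rate, seed=seed)


@dataclass
class DiscriminatorSpec:
    """Discriminator hyperparameters; backbone matches the generative CLM."""

    vocab_size: int
    h1: int = 1024
    h2: int = 256
    lr: float = 1e-3
    epochs: int = 50
    rate: float = 0.15


class ElectraCLM:
    """Per-position corruption discriminator on the shared backbone."""

    def __init__(self, vocab: Vocabulary, spec: DiscriminatorSpec,
                 seed: int = 0):
        if spec.vocab_size != len(vocab):
            raise ShapeMismatch(
                f"spec.vocab_size={spec.vocab_size} != |vocab|={len(vocab)}")
        self.vocab = vocab
        self.spec = spec
        rng = nn._rng(seed)
        self.backbone = nn.Backbone(spec.vocab_size, spec.h1, spec.h2, rng)
        self.head = nn.Dense("disc_head", spec.h2, 1, rng)

    @property
    def layers(self) -> list[nn.Layer]:
        return self.backbone.layers + [self.head]

    def n_parameters(self, include_stats: bool = True) -> int:
        return sum(l.n_parameters(include_stats) for l in self.layers)

    def pretrain(self, corpus: list[list[int]], epochs: int | None = None,
                 rate: float | None = None, batch_size: int = 64,
                 seed: int = 0) -> list[float]:
        """Train replaced-token detection; fresh corruption each epoch."""
        if not corpus:
            raise ValueError("empty corpus")
        rate = self.spec.rate if rate is None else rate
        if rate <= 0:
            raise InvalidTrainingData(
                "corruption rate 0 yields all-negative labels")
        epochs = self.spec.epochs if epochs is None else epochs
        rng = nn._rng(seed)
        ss = np.random.SeedSequence(seed)
        epoch_seeds = ss.generate_state(max(epochs, 1) * len(corpus))
        opt = nn.Adam(self.layers, lr=self.spec.lr)
        pad = self.vocab.pad
        V = self.spec.vocab_size
        history = []
        order = np.arange(len(corpus))
        for epoch in range(epochs):
            rng.shuffle(order)
            total, nb = 0.0, 0
            for lo in range(0, len(order), batch_size):
                rows = order[lo:lo + batch_size]
                seqs, labels = [], []
                for j, i in enumerate(rows):
                    ts = TokenizedString(corpus[i], len(corpus[i]))
                    cseed = int(epoch_seeds[epoch * len(corpus) + i]) & 0x7FFFFFFF
                    cr = corrupt(ts, rate, self.vocab, cseed)
                    seqs.append(cr.corrupted.token_indices)
                    labels.append(cr.labels)
                tok = nn.pad_batch(seqs, pad)
                lab = np.zeros(tok.shape, nn.DTYPE)
                for j, l in enumerate(labels):
                    lab[j, :len(l)] = l
                # train on chemical positions only: specials are never
                # corrupted and padding carries no signal
                special = np.isin(tok, list(self.vocab.special_indices))
                mask = (~special).astype(nn.DTYPE)
                x = nn.one_hot(tok, V)
                feats = self.backbone.forward(x, training=True)
                logits = self.head.forward(feats, training=True)[..., 0]
                loss, dlogits = nn.masked_binary_cross_entropy(
                    logits, lab, mask)
                self.backbone.backward(self.head.backward(dlogits[..., None]))
                opt.step()
                total += loss
                nb += 1
            history.append(total / max(nb, 1))
        return history

    def corruption_scores(self, seqs: list[list[int]]) -> list[np.ndarray]:
        """Per-position probability that each token was substituted."""
        pad = self.vocab.pad
        V = self.spec.vocab_size
        tok = nn.pad_batch(seqs, pad)
        x = nn.one_hot(tok, V)
        feats = self.backbone.forward(x, training=False)
        logits = self.head.forward(feats, training=False)[..., 0]
        scores = 1.0 / (1.0 + np.exp(-logits))
        return [scores[i, :len(s)] for i, s in enumerate(seqs)]

    def save(self, path: str | Path) -> None:
        arch = {"kind": "electra", "vocab": self.vocab.tokens,
                "scheme": self.vocab.scheme,
                "h1": self.spec.h1, "h2": self.spec.h2}
        nn.save_checkpoint(path, arch, self.layers)

    @classmethod
    def load(cls, path: str | Path) -> "ElectraCLM":
        arch, weights = nn.load_weights(path)
        vocab = Vocabulary(tokens=arch["vocab"],
                           scheme=arch.get("scheme", "token"))
        spec = DiscriminatorSpec(vocab_size=len(vocab),
                                 h1=arch["h1"], h2=arch["h2"])
        model = cls(vocab, spec, seed=0)
        for layer in model.layers:
            layer.load_state_dict(weights)
        return model


def pretrain_discriminator(corpus: list[list[int]], vocab: Vocabulary,
                           spec: DiscriminatorSpec | None = None,
                           rate: float = 0.15, epochs: int | None = None,
                           seed: int = 0) -> ElectraCLM:
    """Convenience wrapper: build and pretrain an :class:`ElectraCLM`."""
    spec = spec or DiscriminatorSpec(vocab_size=len(vocab))
    model = ElectraCLM(vocab, spec, seed=seed)
    model.pretrain(corpus, epochs=epochs, rate=rate, seed=seed)
    return model
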