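"""Autoregressive generative chemical language model.

The architecture follows the recurrent design used for SMILES generation:
input feature normalization, an LSTM block of ``h1`` memory cells, an LSTM
block of ``h2`` cells, a second feature normalization, and a per-step dense
softmax projection onto the vocabulary.  With the published widths
(1024/256 cells) and a 71-symbol one-hot vocabulary the total parameter
count, including the normalization statistics, is 5,820,515.

Sampling supports two policies:

* temperature sampling — ``q_i = exp(z_i/T) / sum_j exp(z_j/T)``;
* nucleus (top-p) sampling — at temperature 1, sampling is restricted to
  the minimal highest-probability token prefix whose cumulative probability
  strictly exceeds the nucleus parameter ``p``, renormalized.

Transfer learning keeps the first recurrent block frozen and continues
training at a reduced learning rate, with the normalization layers run in
inference mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .chem_io import MoleculeRecord, Vocabulary, standardize
from .errors import (InvalidNucleus, InvalidTemperature, ShapeMismatch,
                     VocabMismatch)


# ---------------------------------------------------------------------------
# Architecture spec and parameter accounting
# ---------------------------------------------------------------------------

@dataclass
class GenerativeArchitectureSpec:
    """Hyperparameters of the generative CLM.

    ``vocab_size`` is the one-hot width V; ``h1``/``h2`` the LSTM widths.
    Defaults reproduce the full-scale architecture; tests shrink the widths
    keeping the 4:1 ratio.
    """

    vocab_size: int
    h1: int = 1024
    h2: int = 256
    lr_pretrain: float = 1e-3
    lr_transfer: float = 1e-4
    epochs_pretrain: int = 40


def count_parameters(spec: GenerativeArchitectureSpec) -> int:
    """Closed-form total parameter count (trainable + normalization stats).

    4V for the input normalization, 4*h1*(V+h1+1) and 4*h2*(h1+h2+1) for
    the LSTM blocks, 4*h2 for the output normalization, and (h2+1)*V for
    the per-step softmax projection.  Strictly increasing in V.
    """
    V, h1, h2 = spec.vocab_size, spec.h1, spec.h2
    return (4 * V + 4 * h1 * (V + h1 + 1) + 4 * h2 * (h1 + h2 + 1)
            + 4 * h2 + (h2 + 1) * V)


def solve_vocab_size(total: int, h1: int = 1024, h2: int = 256,
                     v_max: int = 500) -> int | None:
    """Invert the closed form: the unique V with the given parameter total."""
    for v in range(1, v_max + 1):
        if count_parameters(GenerativeArchitectureSpec(v, h1, h2)) == total:
            return v
    return None


# ---------------------------------------------------------------------------
# Sampling math
# ---------------------------------------------------------------------------

def temperature_probs(logits: np.ndarray, T: float) -> np.ndarray:
    """Temperature-scaled softmax ``q_i = exp(z_i/T)/sum_j exp(z_j/T)``."""
    if not T > 0:
        raise InvalidTemperature(f"T must be > 0, got {T}")
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return nn.softmax(logits / T)


def nucleus_top_vocab(probs: np.ndarray, p: float) -> np.ndarray:
    """Minimal descending-probability prefix with cumulative mass > p.

    Ties in probability are broken by ascending token index so the prefix
    is deterministic.  Returns the token indices of the top vocabulary.
    """
    if p < 0 or p >= 1:
        raise InvalidNucleus(f"p must lie in [0, 1), got {p}")
    probs = np.asarray(probs, dtype=np.float64)
    order = np.argsort(-probs, kind="stable")
    cum = np.cumsum(probs[order])
    k = int(np.searchsorted(cum, p, side="right")) + 1
    k = min(k, len(order))
    return order[:k]


@dataclass
class SamplingPolicy:
    """Either temperature sampling (parameter T) or nucleus sampling (p)."""

    mode: str                       # "temperature" | "nucleus"
    T: float = 1.0
    p: float = 0.85
    max_len: int = 100              # tokens, incl. start/stop headroom
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("temperature", "nucleus"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "temperature" and not self.T > 0:
            raise InvalidTemperature(self.T)
        if self.mode == "nucleus" and not 0 <= self.p < 1:
            raise InvalidNucleus(self.p)

    @classmethod
    def temperature(cls, T: float, **kw) -> "SamplingPolicy":
        return cls(mode="temperature", T=T, **kw)

    @classmethod
    def nucleus(cls, p: float, **kw) -> "SamplingPolicy":
        return cls(mode="nucleus", p=p, **kw)


@dataclass
class SampledString:
    """One generated string with provenance for auditing."""

    smiles: str
    token_indices: list[int]
    truncated: bool
    # per-step (allowed token indices, chosen index); populated when traced
    trace: list[tuple[np.ndarray, int]] | None = None


@dataclass
class GenerationReport:
    """Validity / uniqueness / novelty of a sampled batch.

    All three percentages use the number of sampled strings as denominator
    by default, so ``pct_novel <= pct_unique <= pct_valid`` always holds;
    the of-valid convention is available via ``denominator="valid"`` in
    :func:`evaluate_generation`.
    """

    n_sampled: int
    pct_valid: float
    pct_unique: float
    pct_novel: float
    molecules: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_sampled": self.n_sampled, "pct_valid": self.pct_valid,
                "pct_unique": self.pct_unique, "pct_novel": self.pct_novel}


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

FREEZE_NAMES = {
    "input-norm": "bn_in",
    "first-recurrent": "lstm1",
    "second-recurrent": "lstm2",
    "output-norm": "bn_out",
    "head": "head",
}


class GenerativeCLM:
    """Recurrent SMILES language model trained with next-token prediction."""

    def __init__(self, vocab: Vocabulary, spec: GenerativeArchitectureSpec,
                 seed: int = 0):
        if spec.vocab_size != len(vocab):
            raise ShapeMismatch(
                f"spec.vocab_size={spec.vocab_size} != |vocab|={len(vocab)}")
        self.vocab = vocab
        self.spec = spec
        rng = nn._rng(seed)
        self.backbone = nn.Backbone(spec.vocab_size, spec.h1, spec.h2, rng)
        self.head = nn.Dense("head", spec.h2, spec.vocab_size, rng)

    # -- plumbing -----------------------------------------------------------
    @property
    def layers(self) -> list[nn.Layer]:
        return self.backbone.layers + [self.head]

    def _layer_by_freeze_name(self, name: str) -> nn.Layer:
        try:
            attr = FREEZE_NAMES[name]
        except KeyError:
            raise ValueError(f"unknown freeze target {name!r}") from None
        return self.head if attr == "head" else getattr(self.backbone, attr)

    def n_parameters(self, include_stats: bool = True) -> int:
        """Framework-reported parameter total of the instantiated network."""
        return sum(l.n_parameters(include_stats) for l in self.layers)

    def _check_corpus(self, corpus: list[list[int]]):
        V = self.spec.vocab_size
        for seq in corpus:
            if any(i < 0 or i >= V for i in seq):
                raise ShapeMismatch("token index out of vocabulary range")

    # -- training -----------------------------------------------------------
    def _train(self, corpus: list[list[int]], epochs: int, lr: float,
               batch_size: int, rng: np.random.Generator,
               on_epoch=None) -> list[float]:
        opt = nn.Adam(self.layers, lr=lr)
        pad = self.vocab.pad
        V = self.spec.vocab_size
        history = []
        order = np.arange(len(corpus))
        for epoch in range(epochs):
            rng.shuffle(order)
            total, nb = 0.0, 0
            for lo in range(0, len(order), batch_size):
                batch = [corpus[i] for i in order[lo:lo + batch_size]]
                tok = nn.pad_batch(batch, pad)
                x = nn.one_hot(tok[:, :-1], V)
                targets = tok[:, 1:]
                mask = (targets != pad).astype(nn.DTYPE)
                feats = self.backbone.forward(x, training=True)
                logits = self.head.forward(feats, training=True)
                loss, dlogits = nn.masked_cross_entropy(logits, targets, mask)
                self.backbone.backward(self.head.backward(dlogits))
                opt.step()
                total += loss
                nb += 1
            history.append(total / max(nb, 1))
            if on_epoch is not None:
                on_epoch(self, epoch)
        return history

    def pretrain(self, corpus: list[list[int]], epochs: int | None = None,
                 batch_size: int = 64, seed: int = 0) -> list[float]:
        """Train from scratch with Adam at the pretraining learning rate."""
        if not corpus:
            raise ValueError("empty corpus")
        self._check_corpus(corpus)
        epochs = self.spec.epochs_pretrain if epochs is None else epochs
        return self._train(corpus, epochs, self.spec.lr_pretrain,
                           batch_size, nn._rng(seed))

    def transfer_learn(self, fine_corpus: list[list[int]], epochs: int,
                       freeze: set[str] = frozenset({"first-recurrent"}),
                       batch_size: int = 32, seed: int = 0,
                       on_epoch=None) -> list[float]:
        """Fine-tune on a small focused corpus.

        Layers named in ``freeze`` keep their parameters bit-identical;
        normalization layers run on their running statistics.  ``on_epoch``
        is invoked after every epoch for epoch-wise sampling protocols.
        """
        self._check_corpus(fine_corpus)
        frozen = [self._layer_by_freeze_name(n) for n in freeze]
        was_trainable = [l.trainable for l in frozen]
        for l in frozen:
            l.trainable = False
        bn_modes = []
        for bn in (self.backbone.bn_in, self.backbone.bn_out):
            bn_modes.append(bn.inference_only)
            bn.inference_only = True
        try:
            history = self._train(fine_corpus, epochs,
                                  self.spec.lr_transfer, batch_size,
                                  nn._rng(seed), on_epoch=on_epoch)
        finally:
            for l, t in zip(frozen, was_trainable):
                l.trainable = t
            for bn, m in zip((self.backbone.bn_in, self.backbone.bn_out),
                             bn_modes):
                bn.inference_only = m
        return history

    def per_token_cross_entropy(self, corpus: list[list[int]],
                                batch_size: int = 64) -> float:
        """Mean next-token cross-entropy (nats) on a corpus, no training."""
        pad = self.vocab.pad
        V = self.spec.vocab_size
        tot, n = 0.0, 0
        for lo in range(0, len(corpus), batch_size):
            tok = nn.pad_batch(corpus[lo:lo + batch_size], pad)
            x = nn.one_hot(tok[:, :-1], V)
            targets = tok[:, 1:]
            mask = (targets != pad).astype(nn.DTYPE)
            feats = self.backbone.forward(x, training=False)
            logits = self.head.forward(feats, training=False)
            loss, _ = nn.masked_cross_entropy(logits, targets, mask)
            tot += loss * mask.sum()
            n += mask.sum()
        return float(tot / max(n, 1))

    # -- generation ---------------------------------------------------------
    def next_token_probs(self, prefix: list[int]) -> np.ndarray:
        """Softmax next-token distribution after consuming ``prefix``."""
        x = nn.one_hot(np.asarray([prefix]), self.spec.vocab_size)
        feats = self.backbone.forward(x, training=False)
        logits = self.head.forward(feats, training=False)
        return nn.softmax(logits[0, -1].astype(np.float64))

    def generate(self, n: int, policy: SamplingPolicy,
                 seed: int | None = None,
                 record_trace: bool = False) -> list[SampledString]:
        """Sample ``n`` strings from start to stop (or ``policy.max_len``)."""
        rng = nn._rng(policy.seed if seed is None else seed)
        vocab = self.vocab
        V = self.spec.vocab_size
        forbid = np.array([vocab.pad, vocab.start])
        out: list[SampledString] = []
        state = self.backbone.init_state(n)
        current = np.full(n, vocab.start, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        seqs: list[list[int]] = [[vocab.start] for _ in range(n)]
        traces: list[list] = [[] for _ in range(n)] if record_trace else None
        for _ in range(policy.max_len):
            if not alive.any():
                break
            h, state = self.backbone.step(nn.one_hot(current, V), state)
            logits = self.head.forward(h, training=False).astype(np.float64)
            logits[:, forbid] = -np.inf
            for i in np.nonzero(alive)[0]:
                if policy.mode == "temperature":
                    finite = np.isfinite(logits[i])
                    probs = np.zeros(V)
                    probs[finite] = temperature_probs(
                        logits[i][finite], policy.T)
                    tok = int(rng.choice(V, p=probs))
                    allowed = None
                else:
                    probs = nn.softmax(logits[i])
                    allowed = nucleus_top_vocab(probs, policy.p)
                    sub = probs[allowed] / probs[allowed].sum()
                    tok = int(allowed[rng.choice(len(allowed), p=sub)])
                if record_trace:
                    traces[i].append(
                        (allowed if allowed is not None else None, tok))
                seqs[i].append(tok)
                if tok == vocab.stop:
                    alive[i] = False
                current[i] = tok
        for i in range(n):
            idx = seqs[i]
            truncated = idx[-1] != vocab.stop
            payload = [t for t in idx if t not in vocab.special_indices]
            smiles = "".join(vocab.tokens[t] for t in payload)
            out.append(SampledString(
                smiles=smiles, token_indices=idx, truncated=truncated,
                trace=traces[i] if record_trace else None))
        return out

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arch = {"kind": "generative", "vocab": self.vocab.tokens,
                "scheme": self.vocab.scheme,
                "h1": self.spec.h1, "h2": self.spec.h2}
        nn.save_checkpoint(path, arch, self.layers)

    @classmethod
    def load(cls, path: str | Path) -> "GenerativeCLM":
        arch, weights = nn.load_weights(path)
        vocab = Vocabulary(tokens=arch["vocab"],
                           scheme=arch.get("scheme", "token"))
        spec = GenerativeArchitectureSpec(
            vocab_size=len(vocab), h1=arch["h1"], h2=arch["h2"])
        model = cls(vocab, spec, seed=0)
        for layer in model.layers:
            layer.load_state_dict(weights)
        return model


# ---------------------------------------------------------------------------
# Generation metrics
# ---------------------------------------------------------------------------

def _canonical_set(records) -> set[str]:
    out = set()
    for r in records:
        out.add(r.canonical_smiles if isinstance(r, MoleculeRecord) else r)
    return out


def evaluate_generation(samples: list[str | SampledString],
                        train_set, fine_set,
                        denominator: str = "sampled") -> GenerationReport:
    """Validity / uniqueness / novelty of a sampled batch.

    A sample is valid if it parses; unique if it is the first occurrence of
    its canonical form among the valid samples; novel if additionally its
    canonical form appears in neither reference set.
    """
    refs = _canonical_set(train_set) | _canonical_set(fine_set)
    seen: set[str] = set()
    mols: list[dict] = []
    n_valid = n_unique = n_novel = 0
    for s in samples:
        smiles = s.smiles if isinstance(s, SampledString) else s
        try:
            canonical = standardize(smiles).canonical_smiles
            valid = True
        except Exception:
            canonical, valid = None, False
        unique = valid and canonical not in seen
        novel = unique and canonical not in refs
        if valid:
            n_valid += 1
            seen.add(canonical)
        n_unique += unique
        n_novel += novel
        mols.append({"smiles": smiles, "canonical": canonical,
                     "valid": valid, "unique": unique, "novel": novel})
    n = len(samples)
    if denominator == "valid":
        den_u = den_n = max(n_valid, 1) if n_valid else None
    elif denominator == "sampled":
        den_u = den_n = n
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    pct = lambda k, d: 0.0 if not d else 100.0 * k / d
    return GenerationReport(
        n_sampled=n,
        pct_valid=pct(n_valid, n),
        pct_unique=pct(n_unique, den_u),
        pct_novel=pct(n_novel, den_n),
        molecules=mols,
    )
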