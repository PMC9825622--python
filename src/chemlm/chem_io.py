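"""Reading, standardizing, filtering and tokenizing SMILES corpora.

The corpus conventions mirror common practice for SMILES language models:
molecules are canonicalized with RDKit, salts are removed by keeping the
largest organic fragment, exact-string duplicates are dropped, and strings
longer than 90 characters are discarded before training.

Tokenization is token-level by default: multi-character atomic symbols
(``Cl``, ``Br``), bracket atoms (``[nH]``, ``[O-]`` ...) and two-digit ring
closures (``%10``) each map to a single vocabulary symbol, so every sampled
index sequence detokenizes to a coherent atom stream.  A strict
character-level scheme is available via ``scheme="char"``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import EmptyAfterStripping, UnknownToken, UnparseableSmiles

RDLogger.DisableLog("rdApp.*")

MAX_SMILES_LEN = 90

# three ordered bioactivity classes (binning rule lives in chemlm.ordinal)


class ActivityClass(IntEnum):
    INACTIVE = 0
    MODERATELY_ACTIVE = 1
    HIGHLY_ACTIVE = 2


@dataclass
class MoleculeRecord:
    """A standardized molecule with optional activity annotation."""

    raw_smiles: str
    canonical_smiles: str
    id: str | None = None
    pIC50: float | None = None
    activity_class: ActivityClass | None = None


def standardize(raw_smiles: str, id: str | None = None,
                pIC50: float | None = None) -> MoleculeRecord:
    """Canonicalize a SMILES string, stripping salts.

    Salt stripping keeps the largest fragment that contains at least one
    carbon atom (ties broken by fragment order).  Raises
    :class:`UnparseableSmiles` for invalid input and
    :class:`EmptyAfterStripping` when no organic fragment remains.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise UnparseableSmiles("empty SMILES string")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise UnparseableSmiles(raw_smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags
               if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        raise EmptyAfterStripping(raw_smiles)
    best = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    canonical = Chem.MolToSmiles(best)
    return MoleculeRecord(raw_smiles=raw_smiles, canonical_smiles=canonical,
                          id=id, pIC50=pIC50)


def filter_corpus(records: Sequence[MoleculeRecord],
                  max_len: int = MAX_SMILES_LEN) -> list[MoleculeRecord]:
    """Drop over-length canonical SMILES and exact-string duplicates.

    Keeps the first occurrence of each canonical string; output order is
    input order.  Idempotent.
    """
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        s = rec.canonical_smiles
        if len(s) > max_len or s in seen:
            continue
        seen.add(s)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

PAD, START, STOP = "<pad>", "<start>", "<stop>"

# bracket atoms, two-digit ring closures and two-letter organic-subset
# elements are single tokens; everything else is one character
_TOKEN_RE = re.compile(r"\[[^\]]*\]|%\d{2}|Cl|Br|.")


def split_smiles(smiles: str, scheme: str = "token") -> list[str]:
    """Split a SMILES string into vocabulary symbols."""
    if scheme == "char":
        return list(smiles)
    if scheme != "token":
        raise ValueError(f"unknown tokenization scheme: {scheme!r}")
    return _TOKEN_RE.findall(smiles)


@dataclass
class Vocabulary:
    """Ordered symbol set shared by the generative and ELECTRA models.

    Index 0/1/2 are reserved for pad/start/stop by the default constructor;
    chemical tokens follow in sorted order.  ``tokens`` lists every symbol
    in index order, so lookup is a bijection.
    """

    tokens: list[str]
    scheme: str = "token"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in (PAD, START, STOP):
            if special not in self.tokens:
                raise ValueError(f"vocabulary lacks special token {special}")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    # -- indices ------------------------------------------------------------
    @property
    def pad(self) -> int:
        return self._index[PAD]

    @property
    def start(self) -> int:
        return self._index[START]

    @property
    def stop(self) -> int:
        return self._index[STOP]

    @property
    def special_indices(self) -> frozenset[int]:
        return frozenset((self.pad, self.start, self.stop))

    @property
    def chemical_indices(self) -> list[int]:
        sp = self.special_indices
        return [i for i in range(len(self.tokens)) if i not in sp]

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise UnknownToken(token) from None

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "tokens": self.tokens,
            "scheme": self.scheme,
            "special": {"pad": self.pad, "start": self.start,
                        "stop": self.stop},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        doc = json.loads(text)
        return cls(tokens=doc["tokens"], scheme=doc.get("scheme", "token"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text())


@dataclass
class TokenizedString:
    """Integer-encoded SMILES: ``[start, payload..., stop]`` before padding."""

    token_indices: list[int]
    length: int  # number of indices excluding padding


def build_vocabulary(records: Iterable[MoleculeRecord | str],
                     scheme: str = "token") -> Vocabulary:
    """Collect all symbols occurring in the corpus plus pad/start/stop."""
    symbols: set[str] = set()
    for rec in records:
        s = rec if isinstance(rec, str) else rec.canonical_smiles
        symbols.update(split_smiles(s, scheme))
    tokens = [PAD, START, STOP] + sorted(symbols)
    return Vocabulary(tokens=tokens, scheme=scheme)


def tokenize(smiles: str, vocab: Vocabulary) -> TokenizedString:
    """Encode a SMILES string as ``[start, symbols..., stop]``."""
    idx = [vocab.start]
    idx += [vocab.index(t) for t in split_smiles(smiles, vocab.scheme)]
    idx.append(vocab.stop)
    return TokenizedString(token_indices=idx, length=len(idx))


def detokenize(ts: TokenizedString, vocab: Vocabulary) -> str:
    """Inverse of :func:`tokenize`; drops start/stop/pad markers."""
    out = []
    for i in ts.token_indices:
        if i in vocab.special_indices:
            continue
        if not 0 <= i < len(vocab):
            raise UnknownToken(f"index {i}")
        out.append(vocab.tokens[i])
    return "".join(out)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_smi(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a .smi file: one SMILES per line, optional tab-separated id.

    Lines starting with ``#`` and blank lines are ignored.
    """
    out: list[tuple[str, str | None]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t", 1)
        out.append((parts[0], parts[1] if len(parts) > 1 else None))
    return out


def write_smi(path: str | Path,
              entries: Iterable[MoleculeRecord | str | tuple]) -> None:
    lines = []
    for e in entries:
        if isinstance(e, MoleculeRecord):
            s, eid = e.canonical_smiles, e.id
        elif isinstance(e, tuple):
            s, eid = e
        else:
            s, eid = e, None
        lines.append(f"{s}\t{eid}" if eid else s)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_activity_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read an activity table with columns ``smiles,pIC50`` and standardize."""
    df = pd.read_csv(path)
    if not {"smiles", "pIC50"}.issubset(df.columns):
        raise ValueError("activity CSV must have columns smiles,pIC50")
    return [standardize(row.smiles, pIC50=float(row.pIC50))
            for row in df.itertuples(index=False)]


def load_corpus(path: str | Path, max_len: int = MAX_SMILES_LEN
                ) -> list[MoleculeRecord]:
    """Read, standardize, filter and dedupe a .smi corpus."""
    records = [standardize(s, id=i) for s, i in read_smi(path)]
    return filter_corpus(records, max_len=max_len)
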