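"""Similarity-based virtual screening with reciprocal-rank fusion.

Each query (fine-tuning) molecule ranks the whole library by Tanimoto
similarity on Morgan fingerprints (rank 1 = most similar, dense integer
ranks, ties broken by library order).  The per-query rankings are fused by
the reciprocal sum of ranks, ``S = sum_i 1/rank(x_i)`` over the N queries;
greater S means a better fused position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RankVectorMismatch
from .metrics import fingerprint_matrix, morgan_fingerprint


@dataclass
class FusionScore:
    index: int                  # position in the library
    id: str | None
    S: float
    ranks: list[int]            # per-query rank of this molecule

    @property
    def best_rank(self) -> int:
        return min(self.ranks)


def rank_per_query(library_fps: np.ndarray,
                   query_fp: np.ndarray) -> np.ndarray:
    """Rank every library member by similarity to one query.

    Returns an integer vector where 1 marks the most similar member;
    every member gets a distinct rank, ties broken by library order.
    """
    lib = np.asarray(library_fps, dtype=bool)
    q = np.asarray(query_fp, dtype=bool)
    inter = (lib & q).sum(axis=1)
    union = (lib | q).sum(axis=1)
    sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    order = np.argsort(-sims, kind="stable")
    ranks = np.empty(len(sims), dtype=np.int64)
    ranks[order] = np.arange(1, len(sims) + 1)
    return ranks


def fuse(rank_vectors: list[np.ndarray] | np.ndarray,
         ids: list[str] | None = None) -> list[FusionScore]:
    """Reciprocal-rank fusion ``S = sum_i 1/rank_i``, best first.

    All rank vectors must cover the same library; the result is sorted by
    S descending with input order breaking ties.  Invariant under
    permutation of the query set.
    """
    if len({len(rv) for rv in rank_vectors}) > 1:
        raise RankVectorMismatch("rank vectors differ in library size")
    mat = np.asarray(rank_vectors, dtype=np.float64)
    if mat.ndim != 2:
        raise RankVectorMismatch("expected a list of per-query rank vectors")
    S = (1.0 / mat).sum(axis=0)
    order = sorted(range(mat.shape[1]), key=lambda j: (-S[j], j))
    return [FusionScore(index=j, id=ids[j] if ids else None,
                        S=float(S[j]),
                        ranks=[int(r) for r in mat[:, j]])
            for j in order]


def screen_library(library_smiles: list[str], query_smiles: list[str],
                   ids: list[str] | None = None,
                   radius: int = 2, n_bits: int = 2048) -> list[FusionScore]:
    """End-to-end screen: fingerprints, per-query ranks, fused scores."""
    lib = fingerprint_matrix(library_smiles, radius, n_bits)
    rank_vectors = [rank_per_query(
        lib, morgan_fingerprint(q, radius, n_bits).bits)
        for q in query_smiles]
    return fuse(rank_vectors, ids=ids)
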