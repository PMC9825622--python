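"""Structural analytics for generated molecule libraries.

Covers Morgan fingerprints with Tanimoto similarity, nearest-neighbour
similarity profiles against a reference (fine-tuning) set, Bemis–Murcko
atom and graph scaffolds with novelty percentages, and the Fréchet
distance between Gaussian summaries of molecule-set embeddings.

The Fréchet computation is featurizer-pluggable.  The default featurizer
is a fixed physicochemical descriptor vector, so distances are
internally comparable across runs of this package but are on a different
scale from values computed with a learned neural embedding (e.g. the
ChemNet features behind the published FCD metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import (AcyclicMolecule, DimensionMismatch, LengthMismatch,
                     NonPSDCovariance, UnparseableSmiles)


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto similarity
# ---------------------------------------------------------------------------

@dataclass
class Fingerprint:
    """Fixed-length binary Morgan (circular substructure) fingerprint."""

    bits: np.ndarray
    radius: int = 2
    n_bits: int = 2048


def _mol(smiles_or_mol):
    if isinstance(smiles_or_mol, Chem.Mol):
        return smiles_or_mol
    mol = Chem.MolFromSmiles(smiles_or_mol)
    if mol is None:
        raise UnparseableSmiles(smiles_or_mol)
    return mol


def morgan_fingerprint(smiles_or_mol, radius: int = 2,
                       n_bits: int = 2048) -> Fingerprint:
    """Morgan fingerprint (radius 2, 2048 bits by default)."""
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    arr = np.array(gen.GetFingerprintAsNumPy(_mol(smiles_or_mol)),
                   dtype=np.uint8)
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto index |a AND b| / |a OR b|; defined as 1.0 when both empty."""
    if a.n_bits != b.n_bits or len(a.bits) != len(b.bits):
        raise LengthMismatch(f"{a.n_bits} vs {b.n_bits} bits")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    return 1.0 if union == 0 else inter / union


def fingerprint_matrix(smiles_list, radius: int = 2,
                       n_bits: int = 2048) -> np.ndarray:
    """Stacked fingerprint bit rows, one per molecule."""
    return np.stack([morgan_fingerprint(s, radius, n_bits).bits
                     for s in smiles_list])


def nn_similarity_profile(designs, reference
                          ) -> list[tuple[int, float]]:
    """Nearest reference neighbour of every design.

    Returns per design ``(reference index, Tanimoto similarity)`` where
    the index is the argmax over the reference set (ties broken by
    reference order).
    """
    if not len(reference):
        raise ValueError("empty reference set")
    ref_fps = [morgan_fingerprint(r) for r in reference]
    out = []
    for d in designs:
        fp = morgan_fingerprint(d)
        sims = [tanimoto(fp, r) for r in ref_fps]
        best = int(np.argmax(sims))
        out.append((best, float(sims[best])))
    return out


# ---------------------------------------------------------------------------
# Bemis–Murcko scaffolds
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldPair:
    """Atom scaffold (rings + linkers, atom/bond types kept) and graph
    scaffold (same framework, all atoms carbon, all bonds single)."""

    atom_scaffold: str
    graph_scaffold: str


def scaffolds(smiles_or_mol) -> ScaffoldPair:
    """Bemis–Murcko decomposition; raises for molecules without rings."""
    mol = _mol(smiles_or_mol)
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        raise AcyclicMolecule(Chem.MolToSmiles(mol))
    atom = Chem.MolToSmiles(core)
    generic = MurckoScaffold.MakeScaffoldGeneric(core)
    graph = Chem.MolToSmiles(generic)
    return ScaffoldPair(atom_scaffold=atom, graph_scaffold=graph)


def scaffold_novelty(designs, reference) -> tuple[float, float]:
    """Percent of designs with an atom / graph scaffold absent from the
    reference set.  Acyclic designs are excluded from the denominator."""
    ref_atom, ref_graph = set(), set()
    for r in reference:
        try:
            sp = scaffolds(r)
        except AcyclicMolecule:
            continue
        ref_atom.add(sp.atom_scaffold)
        ref_graph.add(sp.graph_scaffold)
    n = new_atom = new_graph = 0
    for d in designs:
        try:
            sp = scaffolds(d)
        except AcyclicMolecule:
            continue
        n += 1
        new_atom += sp.atom_scaffold not in ref_atom
        new_graph += sp.graph_scaffold not in ref_graph
    if n == 0:
        return 0.0, 0.0
    return 100.0 * new_atom / n, 100.0 * new_graph / n


# ---------------------------------------------------------------------------
# Fréchet distance between embedding summaries
# ---------------------------------------------------------------------------

PHYSCHEM_FEATURIZER_ID = "physchem-v1"

_PHYSCHEM_FUNCS = (
    Descriptors.MolWt,
    Crippen.MolLogP,
    rdMolDescriptors.CalcTPSA,
    rdMolDescriptors.CalcNumHBD,
    rdMolDescriptors.CalcNumHBA,
    rdMolDescriptors.CalcNumRotatableBonds,
    rdMolDescriptors.CalcNumRings,
    rdMolDescriptors.CalcFractionCSP3,
    Descriptors.HeavyAtomCount,
    rdMolDescriptors.CalcNumAromaticRings,
)


def physchem_features(smiles_or_mol) -> np.ndarray:
    """Fixed 10-dimensional physicochemical descriptor vector."""
    mol = _mol(smiles_or_mol)
    return np.array([f(mol) for f in _PHYSCHEM_FUNCS], dtype=np.float64)


@dataclass
class EmbeddingSummary:
    """Gaussian summary (mean, covariance) of a molecule-set embedding."""

    mean: np.ndarray
    cov: np.ndarray
    n: int
    featurizer: str = PHYSCHEM_FEATURIZER_ID


def embedding_summary(smiles_list, featurizer=None,
                      featurizer_id: str | None = None) -> EmbeddingSummary:
    """Summarize a molecule set as a Gaussian in feature space (n >= 2)."""
    fn = featurizer or physchem_features
    fid = featurizer_id or (PHYSCHEM_FEATURIZER_ID if featurizer is None
                            else "custom")
    X = np.stack([fn(s) for s in smiles_list])
    if X.shape[0] < 2:
        raise ValueError("need at least 2 molecules for a covariance")
    return EmbeddingSummary(mean=X.mean(axis=0),
                            cov=np.cov(X, rowvar=False).reshape(
                                X.shape[1], X.shape[1]),
                            n=X.shape[0], featurizer=fid)


def _sqrt_psd(mat: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    scale = max(abs(w).max(), 1.0)
    if w.min() < -tol * scale:
        raise NonPSDCovariance(f"eigenvalue {w.min():.3e}")
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def frechet_distance(s1: EmbeddingSummary, s2: EmbeddingSummary) -> float:
    """Squared Fréchet (Wasserstein-2) distance between two Gaussians.

    ``d^2 = |mu1-mu2|^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})``, computed via the
    symmetric form ``(S2^{1/2} S1 S2^{1/2})^{1/2}`` with negative
    eigenvalues clipped at zero.  Symmetric, zero for identical summaries.
    """
    if s1.featurizer != s2.featurizer:
        raise DimensionMismatch(
            f"featurizers differ: {s1.featurizer} vs {s2.featurizer}")
    if s1.mean.shape != s2.mean.shape:
        raise DimensionMismatch(
            f"dims differ: {s1.mean.shape} vs {s2.mean.shape}")
    mu1, mu2 = np.atleast_1d(s1.mean), np.atleast_1d(s2.mean)
    c1 = np.atleast_2d(s1.cov)
    c2 = np.atleast_2d(s2.cov)
    root2 = _sqrt_psd(c2)
    cross = _sqrt_psd(root2 @ c1 @ root2)
    d2 = float((mu1 - mu2) @ (mu1 - mu2)
               + np.trace(c1) + np.trace(c2) - 2.0 * np.trace(cross))
    return max(d2, 0.0)
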