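"""Self-contained synthetic SMILES corpora with planted activity signal.

Molecules are built by template decoration — a ring scaffold drawn from a
small pool, optionally prefixed and suffixed with substituents — so every
emitted string is valid by construction and scaffold membership is known
ground truth.  An activity set plants a pharmacophore (an aryl
sulfonamide group): molecules carrying it get a pIC50 elevated by a fixed
effect, with Gaussian noise on top, producing three ordered activity
classes in roughly the 34:121:43 proportion of a realistic kinase
screening panel (about 17% inactive / 61% moderate / 22% highly active).

Everything is deterministic per seed; different seeds give different
corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord, filter_corpus, standardize, write_smi
from .ordinal import assign_class

import numpy as np

SCAFFOLD_POOL = [
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "C1CCCCC1",        # cyclohexane
    "C1CCNCC1",        # piperidine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCOCC1",        # tetrahydropyran
]

# prefixes bond their last atom to the scaffold's first ring atom
PREFIX_POOL = ["C", "CC", "CCC", "CC(C)", "CCO", "COC", "OC",
               "CC(=O)", "NC(=O)", "FC(F)(F)"]
# suffixes bond to the scaffold's closing ring atom
SUFFIX_POOL = ["C", "CC", "O", "OC", "N", "CCl", "Br", "CO", "C#N", "C(C)C"]
# bridges joining a second ring system to the first
BRIDGE_POOL = ["", "C", "CC", "O", "CO", "N"]

PHARMACOPHORE_SUFFIX = "S(N)(=O)=O"      # aryl sulfonamide when attached
PHARMACOPHORE_SMARTS = "S(=O)(=O)N"


@dataclass
class FixtureSpec:
    """Study-shaped synthetic data: sizes, decoration rules, activity rule."""

    n_pretrain: int = 2000
    n_activity: int = 198
    n_finetune: int = 43          # focused subset used for transfer learning
    scaffold_pool: list[str] = field(default_factory=lambda: SCAFFOLD_POOL)
    prefix_pool: list[str] = field(default_factory=lambda: PREFIX_POOL)
    suffix_pool: list[str] = field(default_factory=lambda: SUFFIX_POOL)
    bridge_pool: list[str] = field(default_factory=lambda: BRIDGE_POOL)
    p_prefix: float = 0.7
    p_suffix: float = 0.7
    p_second_ring: float = 0.4
    carrier_fraction: float = 0.22   # pharmacophore prevalence (activity set)
    pretrain_carrier_fraction: float = 0.10  # background prevalence
    base_pIC50: float = 4.2
    effect: float = 3.0              # pIC50 lift for carriers
    sigma: float = 0.3               # log-unit noise
    seed: int = 0


def _has_pharmacophore(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmarts(PHARMACOPHORE_SMARTS)
    return mol is not None and mol.HasSubstructMatch(patt)


def _decorate(spec: FixtureSpec, rng: np.random.Generator,
              carrier: bool = False) -> str:
    scaffold = spec.scaffold_pool[int(rng.integers(len(spec.scaffold_pool)))]
    core = scaffold
    if rng.random() < spec.p_second_ring:
        bridge = spec.bridge_pool[int(rng.integers(len(spec.bridge_pool)))]
        second = spec.scaffold_pool[
            int(rng.integers(len(spec.scaffold_pool)))]
        core = scaffold + bridge + second
    prefix = ""
    if rng.random() < spec.p_prefix:
        prefix = spec.prefix_pool[int(rng.integers(len(spec.prefix_pool)))]
    if carrier:
        suffix = PHARMACOPHORE_SUFFIX
    elif rng.random() < spec.p_suffix:
        suffix = spec.suffix_pool[int(rng.integers(len(spec.suffix_pool)))]
    else:
        suffix = ""
    return prefix + core + suffix


def _sample_unique(spec: FixtureSpec, n: int, rng: np.random.Generator,
                   carrier_flags: list[bool] | None = None
                   ) -> list[MoleculeRecord]:
    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    i = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        carrier = carrier_flags[i % len(carrier_flags)] if carrier_flags \
            else False
        raw = _decorate(spec, rng, carrier=carrier)
        try:
            rec = standardize(raw)
        except Exception:
            continue
        if rec.canonical_smiles in seen or len(rec.canonical_smiles) > 90:
            continue
        seen.add(rec.canonical_smiles)
        out.append(rec)
        i += 1
    if len(out) < n:
        raise RuntimeError(
            f"could only build {len(out)}/{n} unique molecules; "
            "enlarge the decoration pools")
    return out


def make_pretrain_corpus(spec: FixtureSpec,
                         path: str | Path | None = None
                         ) -> list[MoleculeRecord]:
    """Valid, standardized, deduplicated pretraining SMILES (seeded).

    The pharmacophore occurs at its background prevalence so the corpus
    covers the chemotype space the activity set is drawn from, as a broad
    pretraining corpus covers the chemotypes of any focused set.
    """
    rng = np.random.default_rng(spec.seed)
    n_carriers = int(round(spec.pretrain_carrier_fraction * spec.n_pretrain))
    flags = [True] * n_carriers + [False] * (spec.n_pretrain - n_carriers)
    rng.shuffle(flags)
    records = _sample_unique(spec, spec.n_pretrain, rng,
                             carrier_flags=flags)
    records = filter_corpus(records)
    if path is not None:
        write_smi(path, records)
    return records


def make_activity_set(spec: FixtureSpec,
                      path: str | Path | None = None
                      ) -> list[MoleculeRecord]:
    """Labelled activity set with planted pharmacophore signal.

    pIC50 = base + effect * [pharmacophore present] + N(0, sigma); the
    substructure is detected on the canonical structure, so labels are
    consistent with what a classifier can actually see.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_activity
    n_carriers = int(round(spec.carrier_fraction * n))
    flags = [True] * n_carriers + [False] * (n - n_carriers)
    rng.shuffle(flags)
    records = _sample_unique(spec, n, rng, carrier_flags=flags)
    for rec in records:
        carrier = _has_pharmacophore(rec.canonical_smiles)
        noise = float(rng.normal(0.0, spec.sigma)) if spec.sigma > 0 else 0.0
        rec.pIC50 = spec.base_pIC50 + spec.effect * carrier + noise
        rec.activity_class = assign_class(rec.pIC50)
    if path is not None:
        pd.DataFrame({
            "smiles": [r.canonical_smiles for r in records],
            "pIC50": [r.pIC50 for r in records],
        }).to_csv(path, index=False)
    return records


def make_finetune_set(spec: FixtureSpec,
                      activity: list[MoleculeRecord] | None = None,
                      path: str | Path | None = None
                      ) -> list[MoleculeRecord]:
    """Focused fine-tuning subset: the most potent activity molecules."""
    activity = activity if activity is not None else make_activity_set(spec)
    ranked = sorted(activity, key=lambda r: -r.pIC50)
    subset = ranked[:spec.n_finetune]
    if path is not None:
        write_smi(path, subset)
    return subset
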