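"""Consistency checks for the deposited study data (optional download).

The study's archived training data (a patent-derived pretraining corpus
and a 198-compound PI3Kγ activity table) can be placed locally and
validated against the published summary statistics: the number of unique
canonical SMILES in the pretraining corpus and the activity-class counts
under the pIC50 cuts 4.0/6.5.  Nothing in the package downloads data.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pandas as pd

from .chem_io import read_smi
from .ordinal import assign_class

#: conventional local location for the deposited archive contents
DEPOSITED_DIR = Path("data/deposited")


def validate_deposited_data(pretrain_smi: str | Path,
                            activity_csv: str | Path) -> dict:
    """Summarize deposited files for comparison with the published counts.

    Returns ``n_unique_smiles`` for the pretraining corpus (expected
    839,674 for the deposited archive) and per-class counts for the
    activity table binned at pIC50 4.0/6.5 (expected 34/121/43).
    The corpus is counted on exact string uniqueness as deposited.
    """
    smiles = [s for s, _ in read_smi(pretrain_smi)]
    n_unique = len(set(smiles))
    df = pd.read_csv(activity_csv)
    counts = Counter(int(assign_class(p)) for p in df["pIC50"])
    return {
        "n_unique_smiles": n_unique,
        "n_inactive": counts.get(0, 0),
        "n_moderately_active": counts.get(1, 0),
        "n_highly_active": counts.get(2, 0),
    }
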