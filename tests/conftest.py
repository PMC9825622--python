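"""Shared fixtures: synthetic corpora and small trained models.

Everything is generated programmatically at test time from seeded
generators; session scope avoids retraining the same small models for
every test.  Tests that mutate a model deep-copy it first.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemlm import fixtures
from chemlm.chem_io import build_vocabulary, tokenize
from chemlm.electra import DiscriminatorSpec, ElectraCLM
from chemlm.generative import GenerativeArchitectureSpec, GenerativeCLM

H1, H2 = 64, 16  # desk-scale widths, keeping the published 4:1 ratio


@pytest.fixture(scope="session")
def fixture_spec():
    return fixtures.FixtureSpec(n_pretrain=400, n_activity=150,
                                n_finetune=30, seed=11)


@pytest.fixture(scope="session")
def pretrain_records(fixture_spec):
    return fixtures.make_pretrain_corpus(fixture_spec)


@pytest.fixture(scope="session")
def activity_records(fixture_spec):
    return fixtures.make_activity_set(fixture_spec)


@pytest.fixture(scope="session")
def finetune_records(fixture_spec, activity_records):
    return fixtures.make_finetune_set(fixture_spec, activity_records)


@pytest.fixture(scope="session")
def vocab(pretrain_records, activity_records, finetune_records):
    return build_vocabulary(pretrain_records + activity_records
                            + finetune_records)


@pytest.fixture(scope="session")
def pretrain_tokens(pretrain_records, vocab):
    return [tokenize(r.canonical_smiles, vocab).token_indices
            for r in pretrain_records]


@pytest.fixture(scope="session")
def finetune_tokens(finetune_records, vocab):
    return [tokenize(r.canonical_smiles, vocab).token_indices
            for r in finetune_records]


@pytest.fixture(scope="session")
def labeled_activity(activity_records, vocab):
    return [(tokenize(r.canonical_smiles, vocab).token_indices,
             r.activity_class) for r in activity_records]


@pytest.fixture(scope="session")
def trained_clm(vocab, pretrain_tokens):
    """Generative model pretrained enough to emit mostly valid SMILES."""
    model = GenerativeCLM(
        vocab, GenerativeArchitectureSpec(len(vocab), h1=H1, h2=H2),
        seed=7)
    model.pretrain(pretrain_tokens, epochs=30, seed=7)
    return model


@pytest.fixture(scope="session")
def trained_eclm(vocab, pretrain_tokens):
    model = ElectraCLM(
        vocab, DiscriminatorSpec(len(vocab), h1=H1, h2=H2), seed=7)
    model.pretrain(pretrain_tokens, epochs=10, rate=0.15, seed=7)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
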