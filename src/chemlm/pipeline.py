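"""End-to-end orchestration of the hybrid CLM workflow.

Stages, in order: load or synthesize corpora -> build vocabulary ->
autoregressive pretraining -> transfer learning (with per-epoch sampling)
-> library sampling under the configured policy -> ELECTRA pretraining ->
classifier-ensemble training -> vote ranking -> structural analysis ->
similarity screening.  Every stage failure is re-raised with stage
attribution, all randomness derives from the single run seed, and a run
manifest (config, seeds, output hashes) is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem_io, fixtures, metrics, ordinal, screen
from .chem_io import build_vocabulary, tokenize
from .electra import DiscriminatorSpec, ElectraCLM
from .errors import StageError
from .generative import (GenerativeArchitectureSpec, GenerativeCLM,
                         SamplingPolicy, evaluate_generation)
from .ordinal import ClassifierSpec, ensemble_votes, train_ensemble

log = logging.getLogger("chemlm.pipeline")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    # corpora: file paths, or None to synthesize from the fixture spec
    pretrain_smi: str | None = None
    finetune_smi: str | None = None
    activities_csv: str | None = None
    fixture: fixtures.FixtureSpec | None = None
    # architecture (widths keep the published 4:1 ratio when scaled)
    h1: int = 1024
    h2: int = 256
    # schedules
    epochs_pretrain: int = 40
    epochs_finetune: int = 10
    epochs_electra: int = 50
    electra_rate: float = 0.15
    sample_every: int = 2        # epoch-wise sampling cadence
    sample_per_epoch: int = 0    # strings sampled at each cadence point (0=off)
    n_sample: int = 5000
    policy_mode: str = "nucleus"
    nucleus_p: float = 0.85
    temperature: float = 0.7
    max_len: int = 100
    # ensemble
    ensemble_size: int = 100
    classifier_epochs: int = 200
    threshold: float = 0.4
    oversample_add: int = 40
    dropout: float = 0.2
    confidence: int | None = None    # vote cutoff for the refined library

    @classmethod
    def small_preset(cls, out_dir: str, seed: int = 0) -> "RunConfig":
        """Desk-scale preset: same structure, shrunk sizes and schedules."""
        return cls(
            out_dir=out_dir, seed=seed,
            fixture=fixtures.FixtureSpec(n_pretrain=400, n_activity=150,
                                         n_finetune=30, seed=seed),
            h1=64, h2=16,
            epochs_pretrain=30, epochs_finetune=4, epochs_electra=4,
            sample_every=2, sample_per_epoch=50,
            n_sample=150, ensemble_size=3, classifier_epochs=25,
            oversample_add=20,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        fx = doc.pop("fixture", None)
        cfg = cls(**doc)
        if fx is not None:
            cfg.fixture = fixtures.FixtureSpec(**fx)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(8)]

    # -- stage: corpora -----------------------------------------------------
    stage = "corpora"
    try:
        if config.pretrain_smi:
            pre = chem_io.load_corpus(config.pretrain_smi)
        elif config.fixture:
            pre = fixtures.make_pretrain_corpus(config.fixture,
                                                out / "pretrain.smi")
        else:
            raise FileNotFoundError("no pretraining corpus configured")
        if config.activities_csv:
            # a missing activities file only blocks the classifier stage,
            # so the error is deferred there for correct attribution
            if Path(config.activities_csv).exists():
                activity = chem_io.read_activity_csv(config.activities_csv)
                for r in activity:
                    r.activity_class = ordinal.assign_class(r.pIC50)
            else:
                activity = None
        elif config.fixture:
            activity = fixtures.make_activity_set(config.fixture,
                                                  out / "activities.csv")
        else:
            activity = None
        if config.finetune_smi:
            fine = chem_io.load_corpus(config.finetune_smi)
        elif config.fixture and activity:
            fine = fixtures.make_finetune_set(config.fixture, activity,
                                              out / "finetune.smi")
        else:
            raise FileNotFoundError("no fine-tuning corpus configured")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: vocabulary --------------------------------------------------
    stage = "vocabulary"
    try:
        vocab = build_vocabulary(pre + fine + (activity or []))
        vocab.save(out / "vocabulary.json")
        tok = lambda recs: [tokenize(r.canonical_smiles, vocab).token_indices
                            for r in recs]
        pre_tok, fine_tok = tok(pre), tok(fine)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: pretrain ----------------------------------------------------
    stage = "pretrain"
    try:
        gspec = GenerativeArchitectureSpec(
            vocab_size=len(vocab), h1=config.h1, h2=config.h2,
            epochs_pretrain=config.epochs_pretrain)
        clm = GenerativeCLM(vocab, gspec, seed=seeds[0])
        log.info("pretraining CLM: %d strings, %d epochs",
                 len(pre_tok), config.epochs_pretrain)
        clm.pretrain(pre_tok, seed=seeds[0])
        clm.save(out / "clm_pretrained")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: finetune ----------------------------------------------------
    stage = "finetune"
    try:
        epoch_reports = []

        def on_epoch(model, epoch):
            if config.sample_per_epoch and (epoch + 1) % config.sample_every == 0:
                pol = _policy(config)
                samp = model.generate(config.sample_per_epoch, pol,
                                      seed=seeds[2] + epoch)
                rep = evaluate_generation([s.smiles for s in samp], pre, fine)
                epoch_reports.append({"epoch": epoch + 1, **rep.to_dict()})

        clm.transfer_learn(fine_tok, epochs=config.epochs_finetune,
                           seed=seeds[1], on_epoch=on_epoch)
        clm.save(out / "clm_finetuned")
        if epoch_reports:
            pd.DataFrame(epoch_reports).to_csv(
                out / "finetune_sampling.csv", index=False)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: sample ------------------------------------------------------
    stage = "sample"
    try:
        policy = _policy(config)
        samples = clm.generate(config.n_sample, policy, seed=seeds[3])
        report = evaluate_generation([s.smiles for s in samples], pre, fine)
        (out / "generation_report.json").write_text(
            json.dumps(report.to_dict(), indent=1))
        pd.DataFrame(report.molecules).to_csv(out / "library.csv",
                                              index=False)
        library = [m for m in report.molecules if m["valid"] and m["unique"]]
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: electra -----------------------------------------------------
    stage = "electra"
    try:
        espec = DiscriminatorSpec(vocab_size=len(vocab), h1=config.h1,
                                  h2=config.h2, epochs=config.epochs_electra,
                                  rate=config.electra_rate)
        eclm = ElectraCLM(vocab, espec, seed=seeds[4])
        eclm.pretrain(pre_tok, seed=seeds[4])
        eclm.save(out / "eclm_pretrained")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: classifier-ensemble -----------------------------------------
    stage = "classifier"
    try:
        if activity is None:
            raise FileNotFoundError("activities file required for the "
                                    "classifier stage")
        labeled = [(tokenize(r.canonical_smiles, vocab).token_indices,
                    r.activity_class) for r in activity]
        cspec = ClassifierSpec(vocab_size=len(vocab), h1=config.h1,
                               h2=config.h2, dropout=config.dropout,
                               epochs=config.classifier_epochs,
                               threshold=config.threshold,
                               oversample_add=config.oversample_add)
        members = train_ensemble(vocab, cspec, labeled,
                                 M=config.ensemble_size, backbone=eclm,
                                 base_seed=seeds[5])
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: vote --------------------------------------------------------
    stage = "vote"
    try:
        lib_seq = [tokenize(m["smiles"], vocab).token_indices
                   for m in library]
        votes = ensemble_votes(members, lib_seq)
        vote_df = pd.DataFrame({
            "smiles": [m["canonical"] for m in library],
            "votes": votes,
            "predicted_class": [
                "highly_active" if v == config.ensemble_size else
                ("highly_active" if v > config.ensemble_size // 2
                 else "other") for v in votes],
        })
        vote_df.to_csv(out / "votes.csv", index=False)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: analysis ----------------------------------------------------
    stage = "analysis"
    try:
        fine_smiles = [r.canonical_smiles for r in fine]
        lib_smiles = [m["canonical"] for m in library]
        analysis: dict = {"n_library": len(library)}
        conf = config.confidence if config.confidence is not None \
            else config.ensemble_size
        counts = {c: int((votes >= c).sum())
                  for c in range(0, config.ensemble_size + 1)}
        analysis["n_high_by_confidence"] = counts
        if lib_smiles:
            atom_pct, graph_pct = metrics.scaffold_novelty(lib_smiles,
                                                           fine_smiles)
            profile = metrics.nn_similarity_profile(lib_smiles, fine_smiles)
            analysis.update({
                "pct_new_atom_scaffold": atom_pct,
                "pct_new_graph_scaffold": graph_pct,
                "mean_nn_similarity": float(np.mean([s for _, s in profile])),
                "per_design": [
                    {"smiles": s, "votes": int(v),
                     "nn_similarity": float(sim), "nn_index": int(idx)}
                    for s, v, (idx, sim) in zip(lib_smiles, votes, profile)],
            })
            if len(lib_smiles) >= 2:
                d2 = metrics.frechet_distance(
                    metrics.embedding_summary(
                        [r.canonical_smiles for r in pre]),
                    metrics.embedding_summary(lib_smiles))
                analysis["frechet_d2_vs_pretrain"] = d2
        (out / "analysis.json").write_text(json.dumps(analysis, indent=1))
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage: screen ------------------------------------------------------
    stage = "screen"
    try:
        if lib_smiles:
            scores = screen.screen_library(lib_smiles, fine_smiles)
            pd.DataFrame({
                "id": [s.index for s in scores],
                "smiles": [lib_smiles[s.index] for s in scores],
                "S": [s.S for s in scores],
                "best_rank": [s.best_rank for s in scores],
            }).to_csv(out / "scores.csv", index=False)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- manifest -----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _policy(config: RunConfig) -> SamplingPolicy:
    if config.policy_mode == "nucleus":
        return SamplingPolicy.nucleus(config.nucleus_p,
                                      max_len=config.max_len)
    return SamplingPolicy.temperature(config.temperature,
                                      max_len=config.max_len)
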