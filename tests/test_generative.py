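"""Generative CLM: parameter accounting, sampling math, generation."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from chemlm.errors import InvalidNucleus, InvalidTemperature
from chemlm.generative import (GenerativeArchitectureSpec, GenerativeCLM,
                               SamplingPolicy, count_parameters,
                               evaluate_generation, nucleus_top_vocab,
                               solve_vocab_size, temperature_probs)



class TestParameterCount:
    def test_published_total_at_71_symbols(self):
        """The 1024/256-cell architecture totals 5,820,515 at V=71."""
        assert count_parameters(GenerativeArchitectureSpec(71)) == 5_820_515

    def test_71_is_unique_solution(self):
        assert solve_vocab_size(5_820_515) == 71

    def test_hand_arithmetic_at_v1(self):
        # 4 + 4*1024*1026 + 4*256*1281 + 4*256 + 257
        expected = 4 + 4_202_496 + 1_311_744 + 1_024 + 257
        assert count_parameters(GenerativeArchitectureSpec(1)) == expected

    def test_strictly_increasing_in_vocab_size(self):
        counts = [count_parameters(GenerativeArchitectureSpec(v))
                  for v in range(1, 100)]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("V", [4, 32, 71])
    def test_closed_form_equals_instantiated_network(self, V):
        """Allocating the real full-width network reproduces the formula."""
        from chemlm.chem_io import PAD, START, STOP, Vocabulary
        tokens = [PAD, START, STOP] + [f"t{i}" for i in range(V - 3)]
        spec = GenerativeArchitectureSpec(V)
        model = GenerativeCLM(Vocabulary(tokens), spec, seed=0)
        assert model.n_parameters() == count_parameters(spec)


class TestTemperatureSampling:
    def test_closed_form_two_logits(self):
        q = temperature_probs(np.array([2.0, 0.0]), T=2.0)
        e = np.e
        np.testing.assert_allclose(q, [e / (e + 1), 1 / (e + 1)], atol=1e-12)

    def test_t1_equals_plain_softmax(self, rng):
        z = rng.normal(size=12)
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(temperature_probs(z, 1.0), expected,
                                   atol=1e-12)

    def test_low_temperature_sharpens_to_argmax(self):
        q = temperature_probs(np.array([1.0, 0.0]), T=0.01)
        assert q[0] > 0.999

    @pytest.mark.parametrize("T", [0.0, -1.0])
    def test_nonpositive_temperature_rejected(self, T):
        with pytest.raises(InvalidTemperature):
            temperature_probs(np.array([1.0, 0.0]), T)

    @given(st.lists(st.floats(-20, 20), min_size=2, max_size=15),
           st.floats(0.05, 0.95))
    @settings(max_examples=200, deadline=None)
    def test_sharpening_is_monotone(self, logits, frac):
        """Lowering T never lowers the maximum probability."""
        z = np.array(logits)
        T = 1.0
        lower = frac * T
        assert (temperature_probs(z, lower).max()
                >= temperature_probs(z, T).max() - 1e-12)

    def test_normalization(self, rng):
        for _ in range(20):
            q = temperature_probs(rng.normal(size=8), T=rng.uniform(0.1, 3))
            assert abs(q.sum() - 1.0) < 1e-9
            assert (q >= 0).all()


class TestNucleusTopVocab:
    def test_four_token_example(self):
        probs = np.array([0.5, 0.3, 0.15, 0.05])
        assert set(nucleus_top_vocab(probs, 0.85)) == {0, 1, 2}

    def test_p_zero_is_argmax(self):
        probs = np.array([0.2, 0.5, 0.3])
        assert list(nucleus_top_vocab(probs, 0.0)) == [1]

    def test_three_token_example(self):
        probs = np.array([0.6, 0.3, 0.1])   # C, N, O
        assert set(nucleus_top_vocab(probs, 0.85)) == {0, 1}

    @pytest.mark.parametrize("p", [-0.1, 1.0, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(InvalidNucleus):
            nucleus_top_vocab(np.array([0.5, 0.5]), p)

    def test_tie_break_by_ascending_index(self):
        probs = np.array([0.25, 0.25, 0.25, 0.25])
        assert list(nucleus_top_vocab(probs, 0.4)) == [0, 1]

    def test_minimality_and_coverage_random_vectors(self, rng):
        """Top vocabulary strictly exceeds p; dropping its least-probable
        member does not."""
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            probs = rng.dirichlet(np.ones(n))
            p = float(rng.uniform(0, 0.999))
            top = nucleus_top_vocab(probs, p)
            mass = probs[top].sum()
            assert mass > p
            assert probs[top[:-1]].sum() <= p + 1e-12


class TestGeneration:
    def _degenerate_model(self, vocab):
        """Zero the backbone and rig the head so one token dominates."""
        spec = GenerativeArchitectureSpec(len(vocab), h1=8, h2=4)
        model = GenerativeCLM(vocab, spec, seed=0)
        for layer in model.backbone.layers:
            for k in layer.params:
                layer.params[k][...] = 0.0
        model.head.params["W"][...] = 0.0
        model.head.params["b"][...] = -50.0
        model.head.params["b"][vocab.index("C")] = 50.0
        return model

    def test_degenerate_model_deterministic_output(self, vocab):
        model = self._degenerate_model(vocab)
        for policy in (SamplingPolicy.nucleus(0.85, max_len=10),
                       SamplingPolicy.temperature(0.7, max_len=10)):
            out = model.generate(5, policy, seed=123)
            assert len({s.smiles for s in out}) == 1
            assert all(s.truncated for s in out)  # stop is never reachable

    def test_nucleus_p0_is_greedy(self, trained_clm):
        out = trained_clm.generate(
            5, SamplingPolicy.nucleus(0.0, max_len=50), seed=9,
            record_trace=True)
        for s in out:
            for allowed, chosen in s.trace:
                assert len(allowed) == 1 and chosen == allowed[0]

    def test_trace_audit_zero_out_of_nucleus_tokens(self, trained_clm):
        """Every sampled token is a member of that step's top vocabulary."""
        out = trained_clm.generate(
            100, SamplingPolicy.nucleus(0.85, max_len=60), seed=4,
            record_trace=True)
        assert len(out) == 100
        violations = sum(chosen not in set(allowed)
                         for s in out for allowed, chosen in s.trace)
        assert violations == 0

    def test_generation_count_and_stop_handling(self, trained_clm, vocab):
        out = trained_clm.generate(
            20, SamplingPolicy.nucleus(0.85, max_len=60), seed=5)
        assert len(out) == 20
        for s in out:
            assert s.truncated == (s.token_indices[-1] != vocab.stop)


class TestTransferLearning:
    def test_frozen_block_bit_identical(self, trained_clm, finetune_tokens):
        model = copy.deepcopy(trained_clm)
        before = {k: v.copy()
                  for k, v in model.backbone.lstm1.params.items()}
        others_before = model.backbone.lstm2.params["Wx"].copy()
        model.transfer_learn(finetune_tokens, epochs=10, seed=3)
        for k, v in model.backbone.lstm1.params.items():
            np.testing.assert_array_equal(v, before[k])
        assert not np.array_equal(model.backbone.lstm2.params["Wx"],
                                  others_before)

    def test_zero_epochs_leaves_model_unchanged(self, trained_clm,
                                                finetune_tokens):
        model = copy.deepcopy(trained_clm)
        probe = finetune_tokens[0]
        before = trained_clm.next_token_probs(probe)
        model.transfer_learn(finetune_tokens, epochs=0, seed=3)
        np.testing.assert_array_equal(model.next_token_probs(probe), before)

    def test_finetuning_biases_sampling_toward_target_scaffold(
            self, trained_clm, vocab, pretrain_records):
        """Fine-tuning on a scaffold-biased set raises the fraction of
        sampled molecules containing that scaffold (binomial margin)."""
        from chemlm.chem_io import tokenize
        patt = Chem.MolFromSmarts("c1ccsc1")   # thiophene ring

        def scaffold_fraction(model, n=300):
            out = model.generate(
                n, SamplingPolicy.nucleus(0.85, max_len=60), seed=21)
            hits = total = 0
            for s in out:
                mol = Chem.MolFromSmiles(s.smiles)
                if mol is not None:
                    total += 1
                    hits += mol.HasSubstructMatch(patt)
            return hits / max(total, 1)

        biased = [r for r in pretrain_records
                  if Chem.MolFromSmiles(r.canonical_smiles)
                  .HasSubstructMatch(patt)][:40]
        assert len(biased) >= 20
        seqs = [tokenize(r.canonical_smiles, vocab).token_indices
                for r in biased]
        model = copy.deepcopy(trained_clm)
        base = scaffold_fraction(model)
        model.transfer_learn(seqs, epochs=15, seed=3)
        tuned = scaffold_fraction(model)
        # ~10pp margin is several binomial SDs at ~150 valid samples
        assert tuned > base + 0.10


class TestPretraining:
    def test_loss_beats_uniform_baseline(self, trained_clm, pretrain_tokens):
        """Per-token cross-entropy falls well below ln(V) after training."""
        uniform = np.log(len(trained_clm.vocab))
        assert trained_clm.per_token_cross_entropy(
            pretrain_tokens[:100]) < uniform

    def test_loss_decreases_over_epochs(self, vocab, pretrain_tokens):
        spec = GenerativeArchitectureSpec(len(vocab), h1=16, h2=4)
        model = GenerativeCLM(vocab, spec, seed=1)
        history = model.pretrain(pretrain_tokens[:150], epochs=5, seed=1)
        assert history[-1] <= history[0]


class TestEvaluateGeneration:
    def test_copy_of_training_set_has_zero_novelty(self, pretrain_records):
        samples = [r.canonical_smiles for r in pretrain_records[:20]]
        rep = evaluate_generation(samples, pretrain_records, [])
        assert rep.pct_novel == 0.0
        assert rep.pct_valid == 100.0

    def test_all_invalid_gives_zeros(self):
        rep = evaluate_generation(["C1CC", ")(", "xx"], [], [])
        assert (rep.pct_valid, rep.pct_unique, rep.pct_novel) == (0, 0, 0)

    def test_hand_counted_fixture(self):
        # 10 samples: 8 valid, 6 distinct canonical, 5 not in references
        refs = ["CCO"]
        samples = ["CCO", "OCC",          # valid, same canonical, in refs
                   "CC", "CC",            # valid dup
                   "CCC", "CCCC", "CCN", "CCS",   # valid distinct novel
                   "C1CC", "(("]          # invalid
        rep = evaluate_generation(samples, refs, [])
        assert rep.pct_valid == 80.0
        assert rep.pct_unique == 60.0
        assert rep.pct_novel == 50.0

    def test_percentage_ordering_invariant(self, trained_clm,
                                           pretrain_records,
                                           finetune_records):
        out = trained_clm.generate(
            60, SamplingPolicy.temperature(1.0, max_len=60), seed=13)
        rep = evaluate_generation([s.smiles for s in out],
                                  pretrain_records, finetune_records)
        assert rep.pct_novel <= rep.pct_unique <= rep.pct_valid <= 100.0
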