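# Methods

## Models

### Generative chemical language model

The generative model is an autoregressive recurrent network over tokenized
SMILES. Its layer plan is: per-feature batch normalization of the one-hot
input, an LSTM block of `h1` memory cells, an LSTM block of `h2` cells, a
second batch normalization, and a per-step dense projection to the
vocabulary with softmax. Training minimizes categorical cross-entropy of
next-token prediction with Adam (learning rate 1e-3, default 40 epochs).
Strings are framed as `start, tokens..., stop`; positions after `stop` are
padded and masked out of the loss.

The total parameter count, counting the normalization layers' moving mean
and variance as parameters alongside their scale/shift (4 per feature), is

    N(V) = 4V + 4·h1·(V + h1 + 1) + 4·h2·(h1 + h2 + 1) + 4·h2 + (h2 + 1)·V

which at the full widths h1 = 1024, h2 = 256 equals 5,820,515 exactly and
uniquely at V = 71 (integer scan over V ≤ 500). The dense output
projection is required for generation even though it is not part of the
four named layers; including it is what reconciles the total, and the
reconciliation is asserted in the tests against the instantiated network.

**Transfer learning** continues training on a small focused corpus at
learning rate 1e-4 with the first recurrent block frozen (its tensors are
bit-identical afterwards, a tested contract). "First layer" is read as the
first LSTM block: freezing the input normalization alone would be nearly
vacuous. The normalization layers run on their running statistics during
fine-tuning so that the small corpus does not perturb them.

### Sampling policies

*Temperature sampling* draws each token from
`q_i = exp(z_i/T)/Σ_j exp(z_j/T)`; T = 1 is plain softmax and T → 0
approaches greedy decoding. *Nucleus sampling* works at T = 1 and keeps
only the minimal descending-probability prefix whose cumulative mass
strictly exceeds the nucleus parameter p (ties broken by ascending token
index for determinism); probabilities inside the nucleus are renormalized
before drawing. With p = 0 the nucleus is the argmax, i.e. greedy
decoding. Generation starts from the start marker and stops at the stop
token or at `max_len` = 100 tokens (the training corpus is capped at 90
characters; the headroom covers start/stop), with truncation flagged.
Sampling can record a per-step trace of the admissible token set, so a
seeded audit can verify that no emitted token ever falls outside its
step's top vocabulary. The pad and start tokens are excluded from
sampling outright.

### ELECTRA-style discriminator (E-CLM)

Replaced-token-detection pretraining corrupts each non-special position
independently with probability `rate` (default 0.15), drawing the
replacement uniformly from the other chemical tokens, and trains the same
backbone plus a per-position sigmoid head with binary cross-entropy (Adam,
1e-3, default 50 epochs) to flag the substituted positions. There is no
generator network — substitutions are uniform random. A fresh corruption
mask is drawn every epoch from a per-epoch derived seed, preventing
memorization of one mask while keeping runs reproducible. The rate 0.15
per position is a choice (only "multiple characters" is implied by the
design); Bernoulli corruption handles short strings without special
cases.

### Ordinal bioactivity classifier and deep ensemble

Activity classes partition pIC50 with boundary values falling to the
lower class: inactive (≤ 4.0), moderately active (4.0, 6.5], highly
active (> 6.5). The classifier is the shared backbone plus dropout (rate
0.2) and three sigmoid units read from the hidden state at the last real
token. The default output coding is cumulative (Frank–Hall): targets
(1,0,0)/(1,1,0)/(1,1,1), preserving class order; prediction scans the
outputs left to right and stops at the first value not exceeding the
sigmoid threshold (0.4), a rule that is monotone in the outputs. A
one-unit-per-class mode is available behind a switch ("highly active" iff
the third unit exceeds the threshold), since the literal three-neuron
description admits that reading too; both modes share the ensemble
machinery.

Class imbalance is addressed by oversampling: the two smallest classes
each gain `add` = 40 uniform-with-replacement copies (ties in class size
break toward the lower ordinal class). Model selection uses k-means
(k = 5) clustering of Morgan fingerprints (Euclidean on 0/1 vectors,
monotone in Hamming distance), with one cluster held out for testing.

The deep ensemble trains M = 100 replicas (desk-scale presets use 3–5)
that differ only in their per-member seed, which drives initialization,
shuffling, dropout and the oversampling draws. A molecule's confidence is
its number of "highly active" votes; ranking at confidence c returns
molecules with ≥ c votes, a set whose size is non-increasing in c.

### Library analytics

Morgan fingerprints use radius 2 and 2048 bits (the community defaults;
the radius/width are configurable). Tanimoto similarity of two empty
fingerprints is defined as 1. Scaffold analysis uses the Bemis–Murcko
decomposition: the atom scaffold keeps atom and bond types of the
ring-plus-linker framework; the graph scaffold erases them (all atoms
carbon, all bonds single), making it invariant under heteroatom
substitution. Acyclic molecules have no scaffold and are excluded from
scaffold-novelty denominators, so "no scaffold" is never counted as "new
scaffold".

The Fréchet distance between two molecule sets summarizes each as a
Gaussian (mean and covariance of an embedding) and reports
`d² = |μ₁−μ₂|² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2})`, computed through the symmetric
form `(Σ₂^{1/2} Σ₁ Σ₂^{1/2})^{1/2}` with eigenvalues clipped at zero
(tolerance 1e-10). The featurizer is pluggable; the default is a fixed
10-dimensional physicochemical descriptor vector. Distances are therefore
internally comparable across runs of this package but are **not** on the
scale of published values computed with a learned neural embedding
(ChemNet); no such weights are shipped.

### Virtual screening

Each query molecule ranks the entire library by Tanimoto similarity
(rank 1 = most similar; dense distinct integer ranks; ties broken by
library order, documented because the fused score is sensitive to rank
integers). The fused score is the reciprocal rank sum `S = Σᵢ 1/rank(xᵢ)`
over the N queries — invariant under query permutation, strictly
increased by improving any single rank, and maximal at S = N for a
molecule every query ranks first.

### Dose–response fitting

Binding curves use the Hill equation with the slope fixed at −1, where
`Kd^slope/Dose^slope` reduces to `Dose/Kd`:

    Response = Background + (Signal − Background) / (1 + Dose/Kd)

The response passes the midpoint exactly at Dose = Kd. Parameters
(Kd, Background, Signal) are estimated by unweighted nonlinear least
squares with Levenberg–Marquardt, fitting log10(Kd) so positivity is
unconstrained; standard errors come from the Jacobian covariance with the
delta method for Kd. Starting values: background = min(response),
signal = max(response), Kd = dose nearest the half-range crossing.
Constant responses and non-converged fits raise instead of returning an
unidentifiable Kd. Doses are molar internally; the CLI and
`from_dataframe` accept nM.

The simulated titration defaults to an 11-point three-fold dilution from
30 µM (0.5 nM–30 µM), the range commercial kinase-binding panels use to
bracket sub-micromolar Kd values, with proportional Gaussian noise (a
coefficient of variation, the usual error model for plate readouts).
Under that design, noiseless data at Kd = 650 nM is recovered to well
under 1%, and 5% CV noise gives a median relative error of about 6% over
20 seeded replicates.

## Synthetic data

The fixture generator builds molecules by template decoration: a ring
scaffold from an 8-member pool (benzene, pyridine, furan, thiophene,
cyclohexane, piperidine, naphthalene, tetrahydropyran), optionally a
bridge plus a second ring, an optional prefix and suffix substituent.
Because every fragment combination is chemically sensible, validity is
guaranteed by construction (and re-verified by standardization), and
scaffold membership is known ground truth for novelty tests.

The activity rule plants a pharmacophore — an aryl sulfonamide suffix —
and sets `pIC50 = 4.2 + 3.0·[pharmacophore present] + N(0, 0.3)`, with a
22% carrier fraction in the activity set (n = 198 by default). The
presence flag is detected on the canonical structure by SMARTS, so labels
are always consistent with what a sequence model can see. These defaults
give roughly 20% inactive / 58% moderately active / 22% highly active,
approximating a realistic kinase panel's 34:121:43 shape, with crisp but
noisy class boundaries. The pretraining corpus carries the pharmacophore
at a 10% background rate so that the focused set lies inside the
pretraining chemical space, as a broad corpus covers the chemotypes of
any focused subset.

What the fixtures do **not** emulate: the property distributions of real
patent chemistry, stereochemistry, charged/bracket-atom tokens, and
activity cliffs (the label rule is a single-substructure threshold).
Passing tests therefore demonstrate the machinery end to end and the
relative behaviour of the two pretraining schemes on detectable
substructure signal — not absolute performance on real assay data.

## Desk-scale problem sizes

Tests and the small pipeline preset run with: 400-molecule pretraining
corpus (2,000 for the discriminator example), 150–198-molecule activity
sets, widths 64/16 (4:1 as in the full architecture), 25–40 training
epochs, ensembles of 3–5 members, and 150-string sampling batches. The
pretraining-strategy benchmark uses 10 replicates with fresh data per
replicate; each compares E-CLM- and CLM-backed ensembles at a matched
true-positive rate of 70% scanned over vote cutoffs. These sizes are the
package's chosen test conditions; every schedule and width is
configurable up to the full-scale settings (p = 0.85 nucleus, 100
members, 200 classifier epochs, +40 oversampling), which are the
defaults of the production `RunConfig`.

## Numerical choices

- All network arithmetic is float32; gradient correctness is verified in
  float64 against central differences (worst relative error ~1e-7).
- Batch normalization uses eps = 1e-3 (one-hot inputs make per-feature
  variances small) and momentum 0.9 on running statistics.
- LSTM forget-gate biases initialize to 1; weights are Glorot-uniform.
- Cross-entropy and BCE losses are masked means over real (non-pad)
  positions; the ELECTRA loss additionally excludes special tokens, which
  are never corrupted.
- Nucleus boundary uses strict `>` with stable descending sort (ties by
  ascending token index).
- The Fréchet matrix square root clips negative eigenvalues at zero and
  rejects covariance matrices with eigenvalues below −1e-10 (scaled).
- All stochastic components consume explicit integer seeds;
  `numpy.random.SeedSequence` derives stage and member seeds, so reruns
  of a pipeline config are bit-identical (manifest hashes are asserted in
  tests).

## Known limitations

- Generation quality at desk scale (≈40% validity after 30 epochs on 400
  molecules) is far from what full-scale training achieves; the tests
  assert invariants and direction, not production-quality rates.
- The voting ensemble is the only uncertainty mechanism (no calibration,
  no Bayesian variants).
- The classifier consumes the canonical SMILES string only; identical
  molecules with different stereochemistry collapse to one record, and
  fingerprints are stereochemistry-blind.
- The Fréchet featurizer is physicochemical, not learned; distances are
  package-internal quantities.
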