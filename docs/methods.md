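# Methods

## Input representation

A record is an RNA sequence over {A,U,G,C} with a nested dot-bracket
secondary structure of equal length. Position *i* is encoded as the dimer
`sequence[i] + structure[i]`; the 12-dimer alphabet is ordered base-major
(`A(`, `A.`, `A)`, `U(`, …, `C)`). That ordering is not intrinsic to the
method, so it is serialized into every model artifact and checked on load —
an encoder/model mismatch is a hard error, never a silent feature permutation.

Records are one-hot encoded to a fixed 180×12 binary matrix. 180 is the
benchmark corpus maximum; it is configurable (`max_len`). Longer inputs are an
error rather than being truncated, because truncation would remove one hairpin
arm while leaving a plausible-looking prefix. Padding rows are all-zero and
are fed to the models as-is (no masking): the CNN is position-weight based and
the LSTM sees a constant-zero input whose only effect on the state is the
documented bias/recurrent drift (verified by a dedicated test). T/t on input
is mapped to U; IUPAC ambiguity codes (including N) are rejected at read time
because the 12-dimer alphabet has no slot for them.

## Secondary structures

Three sources, in order of fidelity:

1. structures already present in an annotated table (`RNAFolds` column);
2. an external folder speaking the RNAfold output dialect (sequence line,
   then dot-bracket with optional ` (energy)` suffix, which is stripped);
3. the built-in Nussinov maximum base-pairing fold.

The built-in folder maximizes the number of nested AU/GC/GU pairs with a
minimum hairpin loop of 3 unpaired bases (the MFE folders' convention). It is
a dependency-free stand-in, not a thermodynamic model: it computes no free
energy and will overpair relative to an MFE structure. Its traceback tie-break
is fixed — position *i* pairs with the largest admissible partner — so output
is bit-stable; the pair count (the quantity the oracle checks) is invariant
under the tie-break. The test suite checks pair-count optimality against an
exhaustive enumeration oracle on short sequences.

## Architectures

**CNN.** conv(16 filters, kernel 4) → pool(2) → conv(32, 5) → pool(2) →
conv(64, 6) → pool(2) → flatten → dense(32, ReLU) → dropout(0.5) →
dense(2) → softmax. Convolutions are 1-D along the sequence with 12 input
channels, `valid` padding (a 2-D kernel spanning the full 12-wide axis would
be mathematically identical). From length 180 the cascade leaves 18 positions
× 64 channels; total 52 690 trainable parameters, a figure the tests derive by
closed-form enumeration.

**RNN.** LSTM(128) → LSTM(64) → LSTM(2), each with 20% dropout applied to its
*inputs* (not the recurrent state), the final 2-unit hidden state feeding the
softmax. The cells are standard no-peephole LSTMs; a peephole (cell-to-output
gate) variant appears in some formulations, but the common library
implementation omits it, and this package follows the library convention —
the deviation is recorded in model metadata (`no_peephole_lstm`). Forget-gate
biases initialize to 1.

Both networks are built on a small NumPy layer library written for this
package (no deep-learning framework backend). Every layer's analytic gradient
is validated against central-difference numerical differentiation in the test
suite, which is the load-bearing correctness argument for hand-written
backprop.

## Training

Mini-batch Adam (defaults: learning rate 1e-3, β₁ 0.9, β₂ 0.999, batch 32) on
the mean cross-entropy, predicted probabilities clipped below at 1e-7 before
the log. Defaults for batch size, learning rate, epoch cap (200) and patience
(10) are conventional values exposed in `TrainingConfig`. Early stopping
monitors validation loss by default and restores the best epoch's weights; a
`training_loss` monitor mode exists for the stricter reading of "stop when the
loss no longer decreases". The per-epoch training loss in the history is the
running mean of the minibatch losses (the usual framework convention), not a
second full pass.

Everything stochastic — initialization, shuffling, dropout, subsampling —
derives from one config seed through a documented fan-out
(`derive_seed(seed, stage)`), so runs are bit-reproducible. Training runs in
float32 (inference follows the stored weight dtype); gradient checks run in
float64. A non-finite loss aborts with a diagnostic rather than training on.

In 10-fold cross-validation there is no standing validation partition, so each
fold carves a seeded 10% out of its nine training folds as the early-stopping
monitor. This keeps the held-out test fold out of model selection at the cost
of slightly less training data per fold.

## Data handling

Balancing draws a seeded, without-replacement negative subsample equal in size
to the positive set. The 3-way split defaults to 0.64/0.16/0.20 with
nearest-integer rounding for validation/test and the remainder to train —
the rule that maps a 3762-record balanced merge to exactly 2408/602/752. The
validation partition's role is fixed: early-stopping monitor and model
selection. Splits and folds stratify by class by default (disable with a
flag); stratified folding falls back to a plain shuffled partition when a
class is smaller than k, where stratification is impossible.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 2TP/(2TP+FP+FN),
MCC (TP·TN−FP·FN)/√((TP+FN)(TN+FP)(TN+FN)(TP+FP)), accuracy
(TP+TN)/N. Zero-denominator conventions: MCC 0, the others NaN. A score
exactly at the 0.5 threshold is called positive — arbitrary but fixed, and
shared between the prediction writer and the confusion tally. ROC and PRC
points are generated at every distinct score, descending; the PRC is anchored
at (recall 0, precision 1); both AUCs use the trapezoidal rule, which for the
ROC equals the Mann–Whitney pairwise concordance statistic (ties half) —
asserted against a brute-force oracle. CV summaries report per-metric mean and
standard error (sample SD/√k). Internal values are fractions; percentages
exist only at the presentation layer. The cross-species report treats an input
table as all-positive and reports the fraction called positive at 0.5.

## Synthetic corpus

The generator emulates the *shape* of the benchmark data, not its biology.
Positives: a random 5′ arm (18–35 nt), a 4–10 nt loop, the arm's reverse
complement, unpaired flanks filling a total length of 60–120 nt, and seeded
mismatches at rate 0.05 that unpair both partners in the recorded structure.
Mutation is capped so the paired fraction never falls below 2·18/120 = 0.30,
making the class-separation property an invariant of the construction.
Negatives: random sequences from a per-record A/C-heavy composition
(A and C cannot pair with each other under Watson–Crick + wobble rules),
rejection-sampled until the Nussinov fold pairs ≤ 35% of bases. A composition
matched to the positives cannot reach that target — maximum base pairing on
uniform random RNA with GU wobble pairs roughly 70% of bases — so weak pairing
is induced compositionally; this is a deliberate design choice, and it means
the synthetic classes differ in base composition as well as structure.

Consequently, passing the recovery tests shows the pipeline is wired correctly
end to end (encoding, training, evaluation) on a strongly separated problem;
it says nothing about accuracy on real pre-miRNAs versus coding-region pseudo
hairpins, whose separation is far subtler. The shared test corpus is 200+200
records at a frozen seed; a default CNN should reach ≥95% held-out accuracy
and the stacked LSTM ≥90%, and in practice both reach ~100%.

## Numerical and degenerate-input choices

- Cross-entropy floor 1e-7 (recorded in model metadata via the training
  config); a confidently wrong prediction costs −log(1e-7) ≈ 16.1.
- Max-pool drops a trailing odd element (floor semantics).
- Glorot-uniform initialization everywhere; forget-gate bias 1.
- Empty tables, unlabeled records for training, mismatched
  structure/sequence lengths, unknown dimers, over-length records and
  unbalanced brackets are all located, record-identified errors — nothing is
  silently dropped.

## Problem sizes

The test suite and the acceptance script run the full protocol at desk scale:
the 400-record synthetic corpus for train/test recovery and 10-fold CV,
exhaustive folding oracles at ≤15 nt (where enumeration is exact), and the
benchmark partition arithmetic at the real sizes (1881/8492 records) with
lightweight placeholder sequences, since the arithmetic depends only on
counts. Training the real benchmark requires the supplementary tables; the
pipeline accepts them unchanged through `premirnet prepare`.

## Known limitations

- The built-in fold is maximum-pairing, not MFE; structures for unannotated
  sequences differ from RNAfold's and the model input distribution shifts
  accordingly. Use the external adapter for fidelity.
- No masking of padded LSTM time steps by default (matching the fixed-length
  input design); very short sequences therefore incur a long pad drift.
- The synthetic negatives' compositional skew makes the synthetic task easier
  than the real one by design.
- No homology-aware splitting: near-duplicate hairpins can land on both sides
  of a split, as in the original protocol.
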