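# premirnet

Detection of human microRNA precursors (pre-miRNAs) from RNA sequence plus
predicted secondary structure, using small deep neural networks and no
hand-crafted features.

## The problem

miRNA genes are excised from ~60–180 nt hairpin precursors. Genomic scans
produce huge numbers of hairpin-like candidates ("pseudo hairpins", typically
drawn from protein-coding regions), so classifiers that separate genuine
precursors from pseudo hairpins are a standard tool in miRNA discovery.
Classical approaches feed dozens of expert-designed descriptors into an SVM or
decision tree; this package instead learns features directly from the raw
sequence/structure string.

## The method

Each position of an RNA sequence is merged with its dot-bracket structure
symbol into a *dimer* — e.g. base `G` paired toward 3′ becomes `G(`. With 4
bases × 3 structure symbols this gives a 12-letter alphabet. A sequence of
length L ≤ 180 becomes a one-hot matrix **X ∈ {0,1}^(180×12)** (zero rows pad
positions beyond L). Two classifiers map X to a softmax probability pair
(p_pseudo, p_precursor):

- **CNN** — three cascades of 1-D convolution + max-pool
  (filters/kernels 16/4, 32/5, 64/6; pool 2), then a 32-unit dense layer with
  dropout 0.5 and a 2-way softmax.
- **RNN** — three stacked LSTM layers of 128, 64 and 2 units with 20% input
  dropout; the final 2-unit state feeds the softmax.

Training minimizes the cross-entropy `−Σᵢ yᵢ log sᵢ` with Adam, monitors
validation loss and restores the best epoch. Evaluation reports sensitivity,
specificity, F1, MCC and accuracy from the confusion matrix, plus ROC/PRC
curves with trapezoidal AUC, and 10-fold cross-validation summaries as
mean ± standard error.

Structures come from the benchmark tables' `RNAFolds` column, from an external
folder (RNAfold output dialect), or from the built-in Nussinov
maximum-base-pairing fold (AU/GC/GU pairs, minimum loop 3). The neural-network
core (convolution, LSTM, backprop, Adam) is implemented in NumPy and verified
against numerical gradients in the test suite.

A synthetic-data module generates hairpin-like positives (complementary stems,
short loops, seeded mismatches) and weakly pairing negatives with consistent
structures and labels, so the whole pipeline is testable with no downloads.

## Worked example

```python
import premirnet as pm
from premirnet.models import positive_scores

corpus = pm.fixture_corpus()                      # 400 labeled synthetic hairpins
train, val, test = pm.split(corpus, pm.SplitSpec(seed=1))
cnn, history = pm.train(pm.build_cnn(),
                        pm.encode_table(train), pm.encode_table(val),
                        pm.TrainingConfig(seed=1))
mats, labels = pm.encode_table(test)
scores = positive_scores(cnn, mats)
m = pm.metrics(pm.confusion(labels, scores))
roc, prc = pm.roc_prc(labels, scores)
print(f"test accuracy {m.accuracy:.3f}  MCC {m.mcc:.3f}  ROC AUC {roc.auc:.3f}")
```

prints

```
test accuracy 1.000  MCC 1.000  ROC AUC 1.000
```

— on the synthetic corpus the stem/loop signal is constructed to be strong, so
a correctly wired classifier should separate the classes essentially
perfectly; anything materially below 1.0 indicates an encoding or training
defect, not a hard dataset.

The same pipeline is available from the shell:

```
premirnet generate --n-pos 200 --n-neg 200 --seed 1 --out corpus.csv
premirnet prepare  --table corpus.csv --seed 1 --out prep/
premirnet train    --prepared prep/ --model cnn --seed 1 --out run/
premirnet predict  --model run/model --input hairpins.fa --out pred.csv
```

To train on the published human benchmark, supply the positive (1881 miRBase
pre-miRNAs) and negative (8492 coding-region pseudo hairpins) annotated tables
— columns `sequence`, `RNAFolds`, optional `id`/`label` — via
`premirnet prepare --positives ... --negatives ...`; balancing, the
2408/602/752 split and 10-fold CV then reproduce the published protocol. Those
tables are not redistributed here; tests that need them look under `data/`
(`data/human_pre_mirna.csv`, `data/pseudo_hairpin.csv`).

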