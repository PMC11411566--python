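# lncstpred

Predicting the subcellular localization of long non-coding RNAs (lncRNAs)
from primary sequence. lncRNAs localize to distinct compartments — nucleus,
cytoplasm, cytosol, ribosome, exosome — and their function tracks their
location, but experimental localization assays are slow and expensive.
`lncstpred` is a sequence-based classifier for this five-class problem,
aimed at computational biologists who have FASTA sequences with known or
suspected localization labels.

## Method

Each sequence of length *M* is encoded as 257 features:

- **3-mer**: frequencies of the 64 trinucleotides over all *M* − 2
  overlapping windows;
- **3-RF**: for each reading frame *x* ∈ {1, 2, 3}, frequencies of the 64
  trinucleotides over the non-overlapping triplets starting at offset *x*
  (each frame's 64-vector normalized separately);
- **MFE**: the minimum free energy (kcal/mol) of the predicted secondary
  structure, from RNAfold or from a built-in simplified Zuker-style folder.

Localization data are heavily imbalanced (nucleus can outnumber exosome by
more than 40:1), so minority classes are oversampled inside each training
fold with Borderline-SMOTE or ADASYN, and synthetic points are screened by
an ensemble-vote entropy filter before training.

The classifier is a modified multiclass AdaBoost. With weighted error
ε_t of the round-*t* base tree and *k* classes, the round coefficient is

    α_t = ½ ln((1 − ε_t)/ε_t) + ln(k − 1)

Correctly classified samples have their weights multiplied by e^(−α_t),
misclassified ones by e^(+α_t), and weights are renormalized to sum to 1
each round; training stops when α_t ≤ 0. For *k* = 2 this is exactly
classic binary AdaBoost.

Feature importance uses the F-score (between-class over within-class
scatter of each feature), and a secondary-structure analysis tabulates
trinucleotide frequencies inside stem (`(((`/`)))`), loop (`...`), and
junction (mixed) windows of the dot-bracket structure against the uniform
baseline of 100/64 ≈ 1.563%.

## Worked example

```python
import warnings
from lncstpred import (
    benchmark_5class, rnafold_fold, assemble_features, matrix_from_frame,
    equalizing_plan, stratified_kfold_cv,
)

dataset = benchmark_5class(seed=1)          # 403 sequences, 5 classes, 25:1 imbalance
folded = rnafold_fold(dataset.sequences)
mfe = {sid: e for sid, (_, e) in folded.items()}
frame, manifest = assemble_features(dataset, mfe)

X, y, names = matrix_from_frame(frame)
plan = equalizing_plan(y, scale_columns=(names.index("MFE"),), seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")            # folds reduced to 8 for the size-8 class
    report, _ = stratified_kfold_cv(X, y, folds=10, plan=plan,
                                    n_rounds=80, depth=2, seed=1)
print(report.summary())
```

```
overall ACC = 98.26%
macro AUC = 0.997
            TP  FN  FP   TN     Sn     Sp    MCC    AUC
cytoplasm  120   0   5  278 1.0000 0.9823 0.9711 0.9998
cytosol     44   1   0  358 0.9778 1.0000 0.9874 0.9982
exosome      7   1   0  395 0.8750 1.0000 0.9342 0.9997
nucleus    197   3   2  201 0.9850 0.9901 0.9752 0.9914
ribosome    28   2   0  373 0.9333 1.0000 0.9635 0.9939
```

Each row is one localization class in one-vs-rest form: Sn (sensitivity) is
the fraction of that class recovered, Sp (specificity) the fraction of
other-class samples not mislabelled as it, MCC the Matthews correlation of
the binarized problem, and AUC the area under the one-vs-rest ROC. The
size-8 exosome class reaches Sn 0.875 here; without in-fold oversampling it
drops to 0.75 — the minority-class gain the balancing step exists for.

The same pipeline is available from the shell:

```bash
lncstpred simulate --preset benchmark5 --seed 1 --out-prefix sim/bench
lncstpred featurize --fasta sim/bench.fasta --labels sim/bench.labels.tsv \
    --mfe-backend rnafold --out bench.tsv
lncstpred cv --matrix bench.tsv --folds 10 --rounds 80 --seed 1 --out report.json
lncstpred rank-features --matrix bench.tsv --top 10 --out rank.tsv
```

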