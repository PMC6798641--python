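# clpmi — pre-miRNA hairpin identification with a cascaded CNN–BLSTM

`clpmi` classifies RNA sequences as pre-miRNA hairpins or negatives from
two inputs per sequence: the nucleotide string and its secondary
structure in dot-bracket notation (DBN). Both are one-hot encoded
(sequence as L×4 over A/C/G/U, structure as L×3 over `(`/`.`/`)`), passed
through parallel convolution → ReLU → max-pool branches, concatenated
position-wise, fed to a bidirectional peephole LSTM, and classified by a
fully connected head with a sigmoid output. Because real pre-miRNA
collections are heavily imbalanced (roughly 7.4 negatives per positive),
training uses focal loss by default, with class-weighted and plain
cross-entropy as alternatives.

The network is implemented directly in NumPy (forward and backward
passes, Adam optimizer) with optional numba-compiled kernels for the
recurrent scan and the structure folder; no deep-learning framework is
required. A synthetic hairpin generator provides labeled data for
experiments and tests when the curated biological collections are not
available.

## Quick start (Python API)

```python
from clpmi import HairpinClassifier, SyntheticParams, make_dataset, evaluate

train = make_dataset(SyntheticParams(n_pos=150, imbalance_ratio=3.0, seed=0))
test = make_dataset(SyntheticParams(n_pos=50, imbalance_ratio=3.0, seed=1))

clf = HairpinClassifier(epochs=100, random_state=0)
clf.fit(train)

scores = clf.decision_scores(test)
report = evaluate(scores, [rec.label for rec in test])
print(f"SE={report.SE:.3f}  SP={report.SP:.3f}  "
      f"g-mean={report.g_mean:.3f}  AUROC={report.AUROC:.3f}")
```

Output (about 45 s on one CPU):

```
SE=0.980  SP=0.947  g-mean=0.963  AUROC=0.994
```

`HairpinClassifier` is a scikit-learn-style estimator: constructor
arguments are hyperparameters (`get_params`/`set_params`/`clone` work),
`fit` learns, fitted state lives in trailing-underscore attributes
(`network_`, `classes_`, `pad_len_`, `history_`), and `predict_proba` /
`predict` follow sklearn conventions. It accepts a `Dataset`, a list of
`SequenceRecord`s, or plain `(sequence, dot_bracket)` string pairs.

Real data enters through `read_fasta` (sequences), `read_rnafold_output`
(sequences + structures + energies) and `attach_labels` (two-column TSV
of id and 0/1 label). Sequences without structures can be folded with
`fold_nussinov` (built-in, base-pair maximization) or `fold_external`
(RNAfold, minimum free energy).

## Command line

The same pipeline is scriptable via the `clpmi` entry point:

```bash
clpmi simulate --n-pos 150 --imbalance-ratio 3 --seed 0 --out-prefix data/train
clpmi train    --dbn data/train.dbn --labels data/train.labels.tsv \
               --epochs 100 --seed 0 --out model.npz
clpmi evaluate --model model.npz --dbn data/test.dbn \
               --labels data/test.labels.tsv --out report.json
clpmi predict  --model model.npz --fasta new_sequences.fasta --out calls.tsv
clpmi cv       --dbn data/train.dbn --labels data/train.labels.tsv --out cv.json
```

Flags override a `--config config.yaml` file, which overrides defaults;
every run writes a JSON manifest recording the resolved configuration
and seed next to its output.

## Layout

| Module | Contents |
| --- | --- |
| `clpmi.io` | FASTA / DBN / label-manifest / prediction I/O |
| `clpmi.structure` | Nussinov folder, RNAfold wrapper, DBN validation |
| `clpmi.encoding` | one-hot encoding of sequence and structure |
| `clpmi.layers`, `clpmi.network` | conv/pool/BLSTM/BN/dropout layers and the assembled network |
| `clpmi._fast` | optional numba kernels (LSTM scan, Nussinov fill) |
| `clpmi.losses` | focal loss, class-weighted and plain cross-entropy |
| `clpmi.metrics` | SE/SP/PPV/F-score/g-mean/AUROC/AUPR, comparison arithmetic |
| `clpmi.benchmarks` | published benchmark figures used by that arithmetic |
| `clpmi.estimator` | the `HairpinClassifier` sklearn-style estimator |
| `clpmi.pipeline` | stratified splits, cross-validation, test evaluation |
| `clpmi.synth` | synthetic hairpin / decoy generator |
| `clpmi.cli` | `clpmi` command-line interface |

See `docs/methods.md` for the model definition, default
hyperparameters, the synthetic generator's assumptions, and numerical
implementation notes.
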