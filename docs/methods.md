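# Methods

## Problem

Given an RNA sequence and its secondary structure in dot-bracket
notation (DBN), decide whether the sequence is a pre-miRNA hairpin.
Pre-miRNAs are ~60–120 nt stem-loops; the discriminative signal lives in
both the nucleotide composition and the pairing pattern, so the model
consumes both, encoded independently.

## Inputs and encoding

Sequences are normalized to uppercase RNA (T → U); residues outside
{A, C, G, U} become the sentinel `N`. Each example is padded to a common
length `L` (the longest sequence in the training set by default,
capped at `max_len=180`) with an accompanying 0/1 validity mask.

- Sequence: `L×4` one-hot with column order A, C, G, U. `N` encodes as
  an all-zero row that still counts as a valid position.
- Structure: `L×3` one-hot with column order `(`, `.`, `)`.

So `"ACGUU"` encodes as rows `[1,0,0,0],[0,1,0,0],[0,0,1,0],[0,0,0,1],
[0,0,0,1]` and `"(...)"` as `[1,0,0],[0,1,0],[0,1,0],[0,1,0],[0,0,1]`.

Structures come from RNAfold output files, from the `fold_external`
wrapper around an `RNAfold` binary (minimum free energy), or from the
built-in `fold_nussinov` dynamic program (maximum number of nested base
pairs, allowing AU/UA, GC/CG and GU/UG wobble pairs, with a minimum
hairpin loop of 3). Nussinov ignores stacking thermodynamics and is a
surrogate, not a replacement, for MFE folding; it exists so the package
has a dependency-free folder for synthetic data and tests. Its traceback
prefers the leftmost 5′ pairing, making structures deterministic.

## Network

Two parallel branches, one per input matrix:
convolution (valid cross-correlation, stride 1) → ReLU → non-overlapping
max-pool → batch normalization. The branch outputs are concatenated
position-wise and fed to a bidirectional LSTM with peephole connections
(configurable off); the final forward and backward hidden states are
concatenated (2×20 = 40 features), batch-normalized, passed through a
fully connected ReLU layer with dropout, batch-normalized again, and
mapped by a final linear unit with sigmoid to a probability. Scores at
or above 0.5 are called positive.

Padding is handled by masks end to end: convolutions only see windows
fully inside the valid region, pooled masks require a fully valid
window, the LSTM carries state through masked steps unchanged, and
batch-norm statistics exclude masked positions. Trailing padding
provably does not change the output (tested to 1e-12).

### Defaults and rationale

| Parameter | Default | Rationale |
| --- | --- | --- |
| `n_filters` | 16 | small enough for CPU training; enough motif channels for 4-letter alphabets |
| `kernel_len` | 5 | covers a stem/loop boundary context |
| `pool_size` | 2 | halves the sequence axis without losing short motifs |
| `lstm_hidden` | 20 | reference recurrent width (per direction) |
| `fc_hidden` | 256 | reference dense width |
| `dropout_p` | 0.5 | reference regularization rate, train-mode only |
| `l2_lambda` | 1e-4 | weight decay on fully connected weights only |
| `peepholes` | True | gates see the cell state; can be disabled |
| batch-norm | eps 1e-5, EMA momentum 0.99 | standard settings; running stats used in eval mode |
| init | Glorot uniform (dense/conv), orthogonal (recurrent), forget bias 1.0 | conventional choices that keep early gradients healthy |
| optimizer | Adam, lr 0.001, betas 0.9/0.999 | reference training setup |
| `epochs` / `batch_size` | 300 / 128 | reference training protocol (experiments below use fewer) |

## Loss and class imbalance

The default loss is focal loss
`L = (1 − p_y)^γ · (−α_y · log p_y)` with γ = 2 and α = 0.25
(α for positives, 1 − α for negatives), which down-weights easy,
abundant negatives. Alternatives: class-weighted cross-entropy with
weights (0.9, 0.1) for (positive, negative), and plain cross-entropy.
At γ = 0 focal loss reduces exactly to α-weighted cross-entropy; this
identity is tested to 1e-12. Gradients flow through the loss
analytically; a finite-difference check over every parameter tensor
passes at relative error 1e-4 (measured worst ≈ 3.5e-7).

## Evaluation

Threshold metrics at 0.5: sensitivity (SE), specificity (SP), positive
predictive value (PPV), F-score, and g-mean = √(SE·SP). Ranking
metrics: AUROC and AUPR (scikit-learn implementations, verified in
tests against exhaustive threshold-sweep oracles). Training uses a
stratified 10% test holdout and stratified 5-fold cross-validation of
the remainder.

## Synthetic data generator

The generator emulates the *shape* of the real problem — hairpin
positives vs non-hairpin negatives at an adjustable imbalance (default
7.4 negatives per positive) — not real genomic sequence statistics.

Positives: sample a stem of 18–30 bp, a loop of 4–10 nt and flanks of
5–15 nt; the 3′ arm is the reverse complement of the 5′ arm with
per-position mutation probability 0.05 (default), which introduces the
bulges and mismatches real pre-miRNAs have. Lengths land in ~60–120 nt.
Negatives (default mix): uniform random sequences, dinucleotide
shuffles of positives (destroys pairing, preserves composition), and
composition-matched random sequences with GC skew. Structures are
assigned with the Nussinov folder so both classes go through the same
pipeline. Everything derives from one `numpy` seed; generation is
byte-reproducible.

What it does not emulate: conservation, genomic context, expression
evidence, multi-loop structures, or RNAfold thermodynamics. Results on
synthetic data show the pipeline learns pairing-pattern signal; they do
not certify performance on curated biological collections.

## Numerical implementation

The network is float64 NumPy throughout (making finite-difference
gradient checks meaningful). Two hot spots have optional
numba-compiled kernels in `clpmi._fast`, each with a mathematically
identical pure-NumPy fallback chosen automatically when numba is
absent; equivalence of the two paths is unit-tested (1e-12/1e-13
tolerances, bit-identical for the integer DP):

- LSTM time scan (forward and backward). The kernel precomputes input
  projections with one GEMM, scans time steps in compiled code, skips
  masked elements (state carries through; their gradients are provably
  zero), and uses a Cephes-style rational approximation of `exp(x)` for
  x ≤ 0 with a power-of-two lookup table for range reconstruction —
  accurate to ~3e-16 relative error in the used range and substantially
  faster than libm here. Sigmoid and tanh are computed in their
  `exp(−|x|)` forms for stability.
- Nussinov DP fill (O(n³)); the fallback fills anti-diagonals with
  vectorized NumPy. Tracebacks are shared, so structures are identical
  across paths.

Weight-gradient reductions are expressed as GEMMs (`tensordot`/reshaped
matrix products) over contiguous layouts. With these kernels a training
batch of 128 examples at L = 100 takes ~80 ms and the full scaled-down
experiment (six 50-epoch trainings on 4,200 examples) about ten minutes
on one CPU.

Determinism: all randomness (init, batch shuffling, dropout, generator)
derives from explicit seeds; repeated single-threaded runs are
bit-identical, which is asserted in the acceptance suite.

## Problem sizes and limitations

Designed for desk-scale data: thousands of sequences of ≤180 nt on one
CPU. Known limitations:

- No GPU path and no framework autograd; very large datasets or long
  sequences will be slow.
- The Nussinov surrogate over-pairs relative to MFE folding; for real
  data, fold with RNAfold and read its output instead.
- Published benchmark figures bundled in `clpmi.benchmarks` are inputs
  for comparison arithmetic only; this package does not reproduce those
  experiments, which require curated datasets that are not
  redistributable here.
- The synthetic generator's defaults were fixed a priori from the
  documented hairpin geometry; they were not tuned to any metric.
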