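"""Seeded synthetic datasets of hairpin positives and decoy negatives.

Positives are built the way a pre-miRNA looks: a random 5' stem arm, a
short terminal loop, and the reverse complement of the arm as the 3'
arm (with per-position mutations at a configurable rate), wrapped in
random single-stranded flanks. Negatives come in three flavours:
uniform random sequences, dinucleotide-preserving shuffles of positives
(hard decoys, mimicking structured non-miRNA ncRNAs), and
mononucleotide-composition-matched random sequences. The default class
imbalance is 7.4 negatives per positive, matching the ratio of known
non-pre-miRNA to pre-miRNA examples in the standard benchmarks.

Structures are assigned with the built-in base-pair-maximization folder
so the generator needs no external binary.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import Dataset, SequenceRecord
from .structure import fold_nussinov

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
NUCLEOTIDES = "ACGU"

NegMode = Literal["uniform_random", "dinucleotide_shuffle", "composition_matched"]


@dataclass(frozen=True)
class SyntheticParams:
    n_pos: int = 500
    stem_len: tuple[int, int] = (18, 30)
    loop_len: tuple[int, int] = (4, 10)
    flank_len: tuple[int, int] = (5, 15)
    mutation_rate: float = 0.05
    neg_mode: NegMode = "uniform_random"
    imbalance_ratio: float = 7.4
    n_neg: int | None = None  # overrides the ratio when set
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_len", "loop_len", "flank_len"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"{name} range {lo}..{hi} is empty or negative")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.imbalance_ratio <= 0:
            raise ValueError("imbalance_ratio must be positive")

    @property
    def effective_n_neg(self) -> int:
        if self.n_neg is not None:
            return self.n_neg
        return round(self.imbalance_ratio * self.n_pos)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def _random_seq(rng: np.random.Generator, n: int, probs=None) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=n, p=probs))


def make_positive(
    params: SyntheticParams, rng: np.random.Generator, rec_id: str = "pos"
) -> SequenceRecord:
    """One hairpin-forming sequence: flank + arm + loop + rc(arm) + flank."""
    stem = int(rng.integers(params.stem_len[0], params.stem_len[1] + 1))
    loop = int(rng.integers(params.loop_len[0], params.loop_len[1] + 1))
    f5 = int(rng.integers(params.flank_len[0], params.flank_len[1] + 1))
    f3 = int(rng.integers(params.flank_len[0], params.flank_len[1] + 1))
    arm5 = _random_seq(rng, stem)
    arm3 = list(reverse_complement(arm5))
    for i in range(stem):
        if rng.random() < params.mutation_rate:
            arm3[i] = NUCLEOTIDES[int(rng.integers(4))]
    seq = (
        _random_seq(rng, f5)
        + arm5
        + _random_seq(rng, loop)
        + "".join(arm3)
        + _random_seq(rng, f3)
    )
    return SequenceRecord(id=rec_id, seq=seq, label=1)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Permutation preserving the dinucleotide count vector (Altschul-
    Erickson style Eulerian-walk shuffle)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {c: [] for c in set(seq)}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    # randomize successor lists, then fix a last-edge spanning tree to the
    # terminal vertex so the walk uses every edge (Eulerian path condition)
    pyrng = random.Random(int(rng.integers(0, 2**31)))
    last = seq[-1]
    for c in edges:
        pyrng.shuffle(edges[c])
    # build a tree of last-edges pointing toward `last` via random walk
    vertices = [c for c in edges if c != last]
    tree_edge: dict[str, str] = {}
    for v in vertices:
        node = v
        while node != last:
            nxt = pyrng.choice(edges[node])
            tree_edge[node] = nxt
            node = nxt
    for v, w in tree_edge.items():
        edges[v].remove(w)
        edges[v].append(w)  # tree edge placed last
    out = [seq[0]]
    counters = {c: 0 for c in edges}
    node = seq[0]
    total_edges = len(seq) - 1
    for _ in range(total_edges):
        nxt = edges[node][counters[node]]
        counters[node] += 1
        out.append(nxt)
        node = nxt
    return "".join(out)


def make_negative(
    params: SyntheticParams,
    rng: np.random.Generator,
    rec_id: str = "neg",
    positive_pool: list[SequenceRecord] | None = None,
) -> SequenceRecord:
    """One non-hairpin decoy according to ``params.neg_mode``."""
    mode = params.neg_mode
    if mode == "uniform_random":
        lo = 2 * params.stem_len[0] + params.loop_len[0] + 2 * params.flank_len[0]
        hi = 2 * params.stem_len[1] + params.loop_len[1] + 2 * params.flank_len[1]
        n = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, n)
    elif mode in ("dinucleotide_shuffle", "composition_matched"):
        if not positive_pool:
            raise ValueError(f"neg_mode {mode!r} needs a positive pool")
        src = positive_pool[int(rng.integers(len(positive_pool)))]
        if mode == "dinucleotide_shuffle":
            seq = dinucleotide_shuffle(src.seq, rng)
        else:
            counts = np.array([src.seq.count(c) for c in NUCLEOTIDES], dtype=float)
            seq = _random_seq(rng, len(src.seq), probs=counts / counts.sum())
    else:
        raise ValueError(f"unknown neg_mode {mode!r}")
    return SequenceRecord(id=rec_id, seq=seq, label=0)


def make_dataset(params: SyntheticParams, fold: bool = True) -> Dataset:
    """Full labeled dataset: n_pos hairpins plus the decoys implied by the
    imbalance ratio, shuffled, with structures attached when ``fold``."""
    rng = np.random.default_rng(params.seed)
    positives = [
        make_positive(params, rng, rec_id=f"pos{i:05d}") for i in range(params.n_pos)
    ]
    n_neg = params.effective_n_neg
    negatives = [
        make_negative(params, rng, rec_id=f"neg{i:05d}", positive_pool=positives)
        for i in range(n_neg)
    ]
    records = positives + negatives
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    if fold:
        records = [r.with_structure(fold_nussinov(r.seq).structure) for r in records]
    return Dataset(records, name=f"synthetic(seed={params.seed})")
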