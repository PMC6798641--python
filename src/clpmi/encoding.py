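"""One-hot encoding of sequence and structure strings.

A sequence position becomes a 4-vector over the column order A, C, G, U;
a structure position a 3-vector over "(", ".", ")". The sentinel residue
N encodes as the all-zero row. Variable-length inputs are zero-padded on
the 3' end to a shared length L; zero rows lie outside both one-hot
alphabets so padding is unambiguous, and a mask vector records which
positions are real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import Dataset, FormatError, SENTINEL

logger = logging.getLogger(__name__)

SEQ_ALPHABET = "ACGU"
STR_ALPHABET = "(.)"
#: default cap on pad length, covering typical pre-miRNA lengths
DEFAULT_MAX_LEN = 180

_SEQ_INDEX = {c: i for i, c in enumerate(SEQ_ALPHABET)}
_STR_INDEX = {c: i for i, c in enumerate(STR_ALPHABET)}


@dataclass
class EncodedExample:
    """One padded network input: L x 4 sequence, L x 3 structure, mask."""

    seq_matrix: np.ndarray
    str_matrix: np.ndarray
    mask: np.ndarray
    label: Optional[int] = None
    id: str = ""

    @property
    def length(self) -> int:
        return int(self.mask.sum())


def encode_sequence(
    seq: str, L: int, truncate: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Encode an RNA string as an L x 4 one-hot matrix plus mask.

    The sentinel residue ``N`` yields an all-zero row (still masked as a
    real position). Sequences longer than L raise unless ``truncate``.
    """
    if len(seq) > L:
        if not truncate:
            raise ValueError(
                f"sequence length {len(seq)} exceeds pad length {L}; "
                "set truncate=True to clip"
            )
        logger.warning("truncating sequence of length %d to %d", len(seq), L)
        seq = seq[:L]
    mat = np.zeros((L, 4), dtype=np.float64)
    mask = np.zeros(L, dtype=np.float64)
    for i, ch in enumerate(seq):
        mask[i] = 1.0
        if ch == SENTINEL:
            continue
        try:
            mat[i, _SEQ_INDEX[ch]] = 1.0
        except KeyError:
            raise FormatError(f"invalid residue {ch!r} at position {i}") from None
    return mat, mask


def encode_structure(
    structure: str, L: int, truncate: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a dot-bracket string as an L x 3 one-hot matrix plus mask."""
    if len(structure) > L:
        if not truncate:
            raise ValueError(
                f"structure length {len(structure)} exceeds pad length {L}"
            )
        structure = structure[:L]
    mat = np.zeros((L, 3), dtype=np.float64)
    mask = np.zeros(L, dtype=np.float64)
    for i, ch in enumerate(structure):
        mask[i] = 1.0
        try:
            mat[i, _STR_INDEX[ch]] = 1.0
        except KeyError:
            raise FormatError(
                f"invalid DBN character {ch!r} at position {i}"
            ) from None
    return mat, mask


def decode_sequence(mat: np.ndarray, mask: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` on the unpadded region."""
    out = []
    for row, m in zip(mat, mask):
        if m == 0:
            break
        hot = np.nonzero(row)[0]
        out.append(SEQ_ALPHABET[hot[0]] if hot.size else SENTINEL)
    return "".join(out)


def decode_structure(mat: np.ndarray, mask: np.ndarray) -> str:
    out = []
    for row, m in zip(mat, mask):
        if m == 0:
            break
        hot = np.nonzero(row)[0]
        out.append(STR_ALPHABET[hot[0]])
    return "".join(out)


def encode_dataset(
    ds: Dataset,
    L: int | None = None,
    max_len: int = DEFAULT_MAX_LEN,
    truncate: bool = False,
) -> list[EncodedExample]:
    """Encode every record of a dataset to a shared pad length.

    ``L=None`` selects the dataset maximum length (capped at
    ``max_len``). Every record must carry a structure.
    """
    missing = [rec.id for rec in ds if rec.structure is None]
    if missing:
        raise ValueError(f"records missing structures: {missing[:5]}")
    if len(ds) == 0:
        return []
    if L is None:
        L = min(max(len(rec.seq) for rec in ds), max_len)
    out = []
    for rec in ds:
        seq_mat, mask = encode_sequence(rec.seq, L, truncate=truncate)
        str_mat, _ = encode_structure(rec.structure, L, truncate=truncate)
        out.append(
            EncodedExample(
                seq_matrix=seq_mat,
                str_matrix=str_mat,
                mask=mask,
                label=rec.label,
                id=rec.id,
            )
        )
    return out


def stack_examples(
    examples: Sequence[EncodedExample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack encoded examples into batch arrays (Xseq, Xstr, mask, y).

    Unlabeled records contribute -1 in the label vector.
    """
    Xseq = np.stack([e.seq_matrix for e in examples])
    Xstr = np.stack([e.str_matrix for e in examples])
    mask = np.stack([e.mask for e in examples])
    y = np.array(
        [e.label if e.label is not None else -1 for e in examples], dtype=np.int64
    )
    return Xseq, Xstr, mask, y
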