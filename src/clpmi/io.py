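"""Reading and writing the file formats the pipeline touches.

Sequences travel as FASTA, secondary structures as dot-bracket notation
(DBN) in RNAfold-style plain text, labels as a two-column TSV manifest,
and predictions as a three-column TSV (id, score, predicted class).

All sequences are normalized to uppercase RNA (T transliterated to U).
Residues outside {A, C, G, U} are kept as the sentinel ``N`` and encode
to an all-zero vector downstream; a warning is logged when they occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
SENTINEL = "N"

#: score >= threshold is called positive
DECISION_THRESHOLD = 0.5


class FormatError(ValueError):
    """A file violated the expected format."""


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence with optional structure and binary label.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    seq : str
        RNA residues over {A, C, G, U} plus the sentinel ``N`` for
        ambiguous positions.
    structure : str, optional
        Dot-bracket string of the same length as ``seq``.
    label : int, optional
        1 = pre-miRNA hairpin, 0 = negative.
    energy : float, optional
        Folding free energy in kcal/mol when parsed from folder output.
    """

    id: str
    seq: str
    structure: Optional[str] = None
    label: Optional[int] = None
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        if len(self.seq) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET - {SENTINEL}
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-RNA characters {sorted(bad)}"
            )
        if self.structure is not None:
            if len(self.structure) != len(self.seq):
                raise FormatError(
                    f"record {self.id!r}: structure length "
                    f"{len(self.structure)} != sequence length {len(self.seq)}"
                )
            _check_balanced(self.structure, self.id)
        if self.label is not None and self.label not in (0, 1):
            raise FormatError(f"record {self.id!r}: label must be 0 or 1")

    def with_structure(self, structure: str) -> "SequenceRecord":
        return replace(self, structure=structure)

    def with_label(self, label: int) -> "SequenceRecord":
        return replace(self, label=label)


def _check_balanced(structure: str, rec_id: str) -> None:
    depth = 0
    for pos, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"record {rec_id!r}: unmatched ')' at position {pos}"
                )
        elif ch != ".":
            raise FormatError(
                f"record {rec_id!r}: invalid DBN character {ch!r} "
                f"at position {pos}"
            )
    if depth != 0:
        raise FormatError(f"record {rec_id!r}: {depth} unclosed '(' brackets")


@dataclass
class Dataset:
    """Ordered collection of records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(positives, negatives) among labeled records."""
        pos = sum(1 for r in self.records if r.label == 1)
        neg = sum(1 for r in self.records if r.label == 0)
        return pos, neg

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    def subset(self, indices: Sequence[int], name: str = "") -> "Dataset":
        return Dataset([self.records[i] for i in indices], name=name or self.name)


def normalize_seq(raw: str, rec_id: str = "?") -> str:
    """Uppercase, transliterate DNA T to U, map other symbols to ``N``."""
    seq = raw.upper().replace("T", "U")
    if set(seq) - RNA_ALPHABET:
        cleaned = "".join(c if c in RNA_ALPHABET else SENTINEL for c in seq)
        logger.warning(
            "record %r: %d ambiguous residues mapped to sentinel %s",
            rec_id, sum(a != b for a, b in zip(seq, cleaned)), SENTINEL,
        )
        seq = cleaned
    return seq


def read_fasta(path: str | Path, name: str = "") -> Dataset:
    """Read a multi-record FASTA file into a Dataset.

    DNA alphabet is transliterated (T -> U) and sequences uppercased.
    Raises :class:`FormatError` on empty sequences or duplicate ids.
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(entry.seq), entry.id)
        if not seq:
            raise FormatError(f"record {entry.id!r}: empty sequence")
        records.append(SequenceRecord(id=entry.id, seq=seq))
    return Dataset(records, name=name or path.stem)


def write_fasta(ds: Dataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ds:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def _parse_structure_line(line: str, rec_id: str) -> tuple[str, Optional[float]]:
    """Split an RNAfold output line into (DBN, energy).

    Accepts ``(((...))) (-1.20)``, ``(((...))) ( -1.20)`` and a bare
    structure with no energy.
    """
    line = line.strip()
    cut = line.find(" ")
    if cut == -1:
        return line, None
    structure, rest = line[:cut], line[cut:].strip()
    if not rest:
        return structure, None
    if not (rest.startswith("(") and rest.endswith(")")):
        raise FormatError(
            f"record {rec_id!r}: malformed energy annotation {rest!r}"
        )
    try:
        energy = float(rest[1:-1].strip())
    except ValueError as exc:
        raise FormatError(
            f"record {rec_id!r}: unparsable energy {rest!r}"
        ) from exc
    return structure, energy


def read_rnafold_output(path: str | Path, name: str = "") -> Dataset:
    """Parse RNAfold plain-text output (header, sequence, structure lines)."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    records = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"expected FASTA header at line {i + 1}, got {header!r}")
        rec_id = header[1:].split()[0] if header[1:].split() else ""
        if i + 2 >= len(lines):
            raise FormatError(f"record {rec_id!r}: truncated entry")
        seq = normalize_seq(lines[i + 1].strip(), rec_id)
        structure, energy = _parse_structure_line(lines[i + 2], rec_id)
        records.append(
            SequenceRecord(id=rec_id, seq=seq, structure=structure, energy=energy)
        )
        i += 3
    return Dataset(records, name=name or path.stem)


def write_rnafold_output(ds: Dataset, path: str | Path) -> None:
    """Write records carrying structures in the RNAfold text dialect."""
    with open(path, "w") as fh:
        for rec in ds:
            if rec.structure is None:
                raise FormatError(f"record {rec.id!r} has no structure")
            suffix = f" ({rec.energy:7.2f})" if rec.energy is not None else ""
            fh.write(f">{rec.id}\n{rec.seq}\n{rec.structure}{suffix}\n")


def read_label_manifest(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of (id, label in {0,1})."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"manifest line {lineno}: expected 2 columns")
        rec_id, raw = parts[0].strip(), parts[1].strip()
        if raw not in ("0", "1"):
            raise FormatError(f"manifest line {lineno}: label must be 0 or 1")
        labels[rec_id] = int(raw)
    return labels


def write_label_manifest(ds: Dataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ds:
            if rec.label is not None:
                fh.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(ds: Dataset, manifest: str | Path | dict) -> Dataset:
    """Join labels onto a dataset by record id.

    Raises if the manifest names ids not present in the dataset.
    """
    labels = manifest if isinstance(manifest, dict) else read_label_manifest(manifest)
    known = {rec.id for rec in ds}
    missing = sorted(set(labels) - known)
    if missing:
        raise FormatError(f"manifest ids absent from dataset: {missing}")
    records = [
        rec.with_label(labels[rec.id]) if rec.id in labels else rec
        for rec in ds
    ]
    return Dataset(records, name=ds.name)


def write_predictions(
    ds: Dataset,
    scores: Iterable[float],
    path: str | Path,
    threshold: float = DECISION_THRESHOLD,
) -> None:
    """Write a TSV of id, score, predicted label at the decision threshold."""
    scores = list(scores)
    if len(scores) != len(ds):
        raise ValueError(
            f"{len(scores)} scores for {len(ds)} records"
        )
    with open(path, "w") as fh:
        fh.write("id\tscore\tpred\n")
        for rec, score in zip(ds, scores):
            pred = int(score >= threshold)
            fh.write(f"{rec.id}\t{score:.6f}\t{pred}\n")
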