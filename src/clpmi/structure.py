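"""Secondary-structure assignment.

Real-data runs should use an external minimum-free-energy folder
(RNAfold); :func:`fold_external` shells out to it. For synthetic data
and dependency-free tests, :func:`fold_nussinov` provides a built-in
base-pair-maximization folder (Nussinov dynamic program). The two
differ — base-pair maximization ignores stacking thermodynamics — but
both emit nested dot-bracket structures over the same alphabet.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import FormatError, _parse_structure_line

try:  # compiled DP fill; the NumPy fallback below is result-identical
    from . import _fast

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in the target env
    _fast = None
    _HAVE_NUMBA = False

#: canonical Watson-Crick pairs plus G-U wobble
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

DEFAULT_MIN_LOOP = 3


class FoldSource(str, Enum):
    EXTERNAL_MFE = "external_mfe"
    NUSSINOV = "nussinov"


class EnvironmentError_(RuntimeError):
    """An external tool was requested but is unavailable or failed."""


@dataclass(frozen=True)
class FoldResult:
    structure: str
    pair_count: int
    source: FoldSource
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.pair_count != self.structure.count("("):
            raise ValueError("pair_count inconsistent with structure")


def can_pair(a: str, b: str) -> bool:
    return (a, b) in ALLOWED_PAIRS


def validate_structure(structure: str) -> list[tuple[int, int]]:
    """Return the matched (i, j) base pairs of a dot-bracket string.

    Uses a stack scan; raises :class:`FormatError` with the offending
    position on unbalanced input.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unmatched ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise FormatError(f"invalid DBN character {ch!r} at position {pos}")
    if stack:
        raise FormatError(
            f"unclosed '(' at position {stack[-1]} (end of string reached)"
        )
    return sorted(pairs)


def _nussinov_fill_numpy(pair_ok: np.ndarray, min_loop: int) -> np.ndarray:
    """NumPy DP fill; same contract as `_fast.nussinov_fill`.

    The table is filled one anti-diagonal (span) at a time as contiguous
    diagonal arrays — diags[s][i] = M[i, i+s] — so every recurrence term
    (i unpaired, or i paired with i+d for offset d > min_loop) is a
    plain slice.
    """
    n = pair_ok.shape[0]
    diags = [np.zeros(n - s, dtype=np.int32) for s in range(n)]
    pair_diag = [
        np.ascontiguousarray(np.diagonal(pair_ok, s)).astype(np.int32)
        for s in range(n)
    ]
    for span in range(min_loop + 1, n):
        width = n - span
        best = diags[span - 1][1 : 1 + width].copy()  # i unpaired: M[i+1, j]
        for d in range(min_loop + 1, span + 1):
            left = diags[d - 2][1 : 1 + width] if d >= 2 else 0
            right = diags[span - d - 1][d + 1 : d + 1 + width] if d < span else 0
            # unpairable offsets contribute 0, never exceeding best >= 0
            np.maximum(best, (1 + left + right) * pair_diag[d][:width], out=best)
        diags[span] = best

    # dense table for the traceback
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for s in range(n):
        idx = np.arange(n - s)
        M[idx, idx + s] = diags[s]
    return M


def fold_nussinov(seq: str, min_loop: int = DEFAULT_MIN_LOOP) -> FoldResult:
    """Maximize the number of nested base pairs (Nussinov DP).

    Allowed pairs are AU/UA, GC/CG and the GU/UG wobble; paired
    positions (i, j) must satisfy j - i > min_loop. Traceback prefers
    pairing the leftmost 5' index so the returned structure is
    deterministic.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")

    # pairability matrix over the numeric alphabet
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    pair_ok = np.zeros((n, n), dtype=bool)
    for a, b in ALLOWED_PAIRS:
        pair_ok |= (code[:, None] == ord(a)) & (code[None, :] == ord(b))

    # M[i, j] = max pairs in seq[i..j]; recurrence: i unpaired, or i pairs
    # with some position k > i + min_loop.
    if _HAVE_NUMBA:
        M = _fast.nussinov_fill(pair_ok.astype(np.uint8), min_loop)
    else:
        M = _nussinov_fill_numpy(pair_ok, min_loop)

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if M[i][j] == M[i + 1][j]:
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    left = M[i + 1][k - 1] if k - 1 > i else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    if M[i][j] == 1 + left + right:
                        structure[i] = "("
                        structure[k] = ")"
                        traceback(k + 1, j)
                        i, j = i + 1, k - 1
                        break
            else:  # pragma: no cover - DP/traceback invariant
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    dbn = "".join(structure)
    return FoldResult(
        structure=dbn, pair_count=int(M[0, n - 1]), source=FoldSource.NUSSINOV
    )


def fold_external(seq: str, binary_path: str = "RNAfold") -> FoldResult:
    """Fold with an external RNAfold-compatible binary (MFE structure).

    Contract: the binary reads the sequence on stdin and writes the
    sequence line followed by ``structure (energy)`` on stdout. Raises
    :class:`EnvironmentError_` (rather than silently falling back) when
    the binary is missing or exits non-zero; callers may then choose
    :func:`fold_nussinov`.
    """
    if shutil.which(binary_path) is None:
        raise EnvironmentError_(
            f"external folder {binary_path!r} not found on PATH; "
            "use fold_nussinov for a dependency-free structure"
        )
    proc = subprocess.run(
        [binary_path, "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise EnvironmentError_(
            f"{binary_path} exited with status {proc.returncode}: "
            f"{proc.stderr.strip()}; use fold_nussinov as fallback"
        )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise EnvironmentError_(f"unexpected {binary_path} output: {proc.stdout!r}")
    structure, energy = _parse_structure_line(lines[-1], "stdin")
    if len(structure) != len(seq):
        raise FormatError(
            f"folder returned structure of length {len(structure)} "
            f"for sequence of length {len(seq)}"
        )
    validate_structure(structure)
    return FoldResult(
        structure=structure,
        pair_count=structure.count("("),
        source=FoldSource.EXTERNAL_MFE,
        energy=energy,
    )
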