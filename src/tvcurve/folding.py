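"""Pluggable secondary-structure prediction backends.

Two backends are provided:

* :class:`RnafoldBackend` shells out to Vienna RNA's ``RNAfold`` and returns
  its minimum-free-energy structure (tool defaults; the energy annotation is
  discarded).
* :class:`NussinovBackend` is a self-contained maximum-base-pairing dynamic
  program with a fixed, deterministic traceback. It is a base-pair
  maximization model, not a thermodynamic one, so its structures differ from
  MFE structures; it exists so every pipeline stage runs deterministically
  with no external tool.

Both satisfy the backend contract: ``fold(seq)`` returns a balanced
dot-bracket string of the same length, deterministically for a fixed input.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from typing import List, Optional, Protocol, Tuple

from .errors import BackendUnavailableError, ValidationError
from .records import RnaRecord, normalize_sequence, pairs_to_dotbracket

logger = logging.getLogger(__name__)

#: Watson-Crick plus GU wobble pairs.
COMPLEMENTARY = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


class FoldingBackend(Protocol):
    """Contract for structure predictors: sequence in, dot-bracket out."""

    name: str

    def fold(self, seq: str) -> str:  # pragma: no cover - protocol stub
        ...


class NussinovBackend:
    """Maximum base pairing by the classic O(N^3) dynamic program.

    Pairs are drawn from {AU, UA, GC, CG, GU, UG}; a hairpin loop must
    enclose at least ``min_loop`` unpaired bases (default 3, the standard
    steric minimum). The traceback tie-break is fixed — prefer leaving the
    left end unpaired, otherwise pair it with the smallest admissible
    partner — so the output is deterministic.
    """

    name = "nussinov"

    def __init__(self, min_loop: int = 3) -> None:
        self.min_loop = min_loop

    def max_pairs(self, seq: str) -> int:
        """Optimal pair count (the DP table's top-right value)."""
        seq = normalize_sequence(seq)
        table, _ = self._fill(seq)
        return table[0][len(seq) - 1] if seq else 0

    def fold(self, seq: str) -> str:
        seq = normalize_sequence(seq)
        n = len(seq)
        if n == 0:
            return ""
        table, _ = self._fill(seq)
        pairs = self._traceback(seq, table)
        return pairs_to_dotbracket({(i + 1, j + 1) for i, j in pairs}, n)

    # -- internals ---------------------------------------------------------

    def _pairable(self, a: str, b: str) -> bool:
        return a + b in COMPLEMENTARY

    def _fill(self, seq: str) -> Tuple[List[List[int]], int]:
        n = len(seq)
        table = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = table[i + 1][j]  # i unpaired
                for k in range(i + self.min_loop + 1, j + 1):
                    if self._pairable(seq[i], seq[k]):
                        inner = table[i + 1][k - 1] if k - 1 > i else 0
                        right = table[k + 1][j] if k + 1 <= j else 0
                        cand = 1 + inner + right
                        if cand > best:
                            best = cand
                table[i][j] = best
        return table, n

    def _traceback(self, seq: str, table) -> List[Tuple[int, int]]:
        pairs: List[Tuple[int, int]] = []
        stack = [(0, len(seq) - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or j - i <= self.min_loop:
                continue
            if table[i][j] == table[i + 1][j]:
                stack.append((i + 1, j))
                continue
            for k in range(i + self.min_loop + 1, j + 1):
                if not self._pairable(seq[i], seq[k]):
                    continue
                inner = table[i + 1][k - 1] if k - 1 > i else 0
                right = table[k + 1][j] if k + 1 <= j else 0
                if table[i][j] == 1 + inner + right:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
        return pairs


class RnafoldBackend:
    """Adapter around Vienna RNA's ``RNAfold`` executable (MFE structure)."""

    name = "rnafold"

    def __init__(self, executable: str = "RNAfold") -> None:
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def fold(self, seq: str) -> str:
        seq = normalize_sequence(seq)
        if not self.available():
            raise BackendUnavailableError(
                f"{self.executable!r} not found on PATH; select the built-in "
                "'nussinov' backend instead"
            )
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
        if len(lines) < 2:
            raise BackendUnavailableError(
                f"unexpected {self.executable} output: {proc.stdout!r}"
            )
        structure = lines[1].split()[0]
        if len(structure) != len(seq):
            raise ValidationError(
                f"{self.executable} returned a structure of length "
                f"{len(structure)} for a sequence of length {len(seq)}"
            )
        return structure


def get_backend(name: Optional[str] = None) -> FoldingBackend:
    """Resolve a backend by name.

    ``None`` selects ``rnafold`` when the executable is on PATH, otherwise
    the built-in ``nussinov`` fallback (with a logged notice).
    """
    if name is None:
        external = RnafoldBackend()
        if external.available():
            return external
        logger.info("RNAfold not found; using the built-in Nussinov backend")
        return NussinovBackend()
    if name == "nussinov":
        return NussinovBackend()
    if name in ("rnafold", "external"):
        backend = RnafoldBackend()
        if not backend.available():
            raise BackendUnavailableError(
                "RNAfold not found on PATH; select the built-in 'nussinov' "
                "backend instead"
            )
        return backend
    raise ValueError(f"unknown folding backend {name!r}")


def ensure_structure(rec: RnaRecord, backend: FoldingBackend) -> RnaRecord:
    """Return the record unchanged if it has a structure, else fold it."""
    if rec.structure is not None:
        return rec
    return rec.with_structure(backend.fold(rec.sequence))
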