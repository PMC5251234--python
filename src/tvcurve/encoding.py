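"""The triple-vector curve (TV-curve) encoding of RNA sequence + structure.

An RNA with a known secondary structure is first rewritten in the 8-letter
characteristic alphabet: A, C, G, U for unpaired bases and A', C', G', U'
(primed) for the same bases when hydrogen-bonded. Each of the eight symbols
maps to a fixed triple of unit steps whose vertical components are +/-1; the
horizontal component is always +1. Concatenating the step triples of all N
symbols and cumulatively summing the vertical components from the origin
yields a 2-D curve of 3N+1 points — the TV-curve. The symbol -> step-triple
map is a bijection, so the curve losslessly encodes both the sequence and
the pairing state of every base.

Note on the C' triple: published tabulations of this map assign the pattern
(+1,-1,-1) to both G and C', which would break the bijection. Seven of the
eight symbols have unambiguous patterns; the only sign pattern they leave
unused is (-1,-1,-1), so C' is assigned that pattern here — the unique
assignment consistent with a one-to-one map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .folding import FoldingBackend
from .records import RnaRecord, SecondaryStructure


class CharacteristicSymbol(NamedTuple):
    """One base annotated with its pairing state (primed <=> paired)."""

    base: str
    paired: bool

    def __str__(self) -> str:
        return self.base + ("'" if self.paired else "")


#: The vertical step components for each of the eight characteristic symbols.
SYMBOL_STEPS: dict[CharacteristicSymbol, Tuple[int, int, int]] = {
    CharacteristicSymbol("A", False): (+1, +1, +1),
    CharacteristicSymbol("A", True): (-1, -1, +1),
    CharacteristicSymbol("U", False): (+1, -1, +1),
    CharacteristicSymbol("U", True): (-1, +1, +1),
    CharacteristicSymbol("G", False): (+1, -1, -1),
    CharacteristicSymbol("G", True): (+1, +1, -1),
    CharacteristicSymbol("C", False): (-1, +1, -1),
    CharacteristicSymbol("C", True): (-1, -1, -1),
}

STEPS_TO_SYMBOL = {v: k for k, v in SYMBOL_STEPS.items()}
assert len(STEPS_TO_SYMBOL) == 8, "symbol -> step-triple map must be a bijection"


def characteristic_representation(
    seq: str, structure: SecondaryStructure
) -> List[CharacteristicSymbol]:
    """Annotate each base of ``seq`` with its pairing state in ``structure``."""
    if len(seq) != len(structure):
        raise ValidationError(
            f"sequence length {len(seq)} != structure length {len(structure)}"
        )
    paired = structure.paired_positions
    return [
        CharacteristicSymbol(base, (i + 1) in paired) for i, base in enumerate(seq)
    ]


def symbol_to_steps(sym: CharacteristicSymbol) -> Tuple[int, int, int]:
    """The three vertical +/-1 steps encoding one characteristic symbol."""
    return SYMBOL_STEPS[sym]


@dataclass(frozen=True)
class TVCurve:
    """The triple-vector curve of one RNA.

    Attributes
    ----------
    steps:
        The 3N vertical step components, each +/-1, in sequence order.
    n:
        Source sequence length N.
    """

    steps: np.ndarray
    n: int

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=np.int64)
        if steps.shape != (3 * self.n,):
            raise ValidationError(
                f"expected {3 * self.n} steps for N={self.n}, got {steps.shape}"
            )
        if not np.all(np.abs(steps) == 1):
            raise ValidationError("curve steps must all be +1 or -1")
        object.__setattr__(self, "steps", steps)

    @property
    def cumulative(self) -> np.ndarray:
        """Curve ordinates y_1..y_{3N} (cumulative sum of the steps)."""
        return np.cumsum(self.steps)

    @property
    def points(self) -> np.ndarray:
        """All 3N+1 curve points (x_k, y_k), starting at the origin."""
        y = np.concatenate(([0], self.cumulative))
        x = np.arange(3 * self.n + 1)
        return np.column_stack((x, y))

    def signal(self, kind: str = "cumulative") -> np.ndarray:
        """The numeric signal handed to the similarity stage."""
        if kind == "cumulative":
            return self.cumulative.astype(float)
        if kind == "steps":
            return self.steps.astype(float)
        raise ValueError(f"unknown signal kind {kind!r}")

    def decode(self) -> List[CharacteristicSymbol]:
        """Invert the encoding back to the characteristic symbol string."""
        return decode_steps(self.steps)


def encode_symbols(symbols: Sequence[CharacteristicSymbol]) -> TVCurve:
    """Encode a characteristic symbol string as a TV-curve."""
    steps = np.fromiter(
        (s for sym in symbols for s in SYMBOL_STEPS[sym]),
        dtype=np.int64,
        count=3 * len(symbols),
    )
    return TVCurve(steps=steps, n=len(symbols))


def encode_tvcurve(
    rec: RnaRecord, backend: Optional[FoldingBackend] = None
) -> TVCurve:
    """Encode one record as a TV-curve; folds first if no structure is given."""
    structure = rec.secondary_structure
    if structure is None:
        if backend is None:
            raise ValidationError(
                f"record {rec.id!r} has no structure and no folding backend "
                "was supplied"
            )
        from .folding import ensure_structure

        rec = ensure_structure(rec, backend)
        structure = rec.secondary_structure
        assert structure is not None
    symbols = characteristic_representation(rec.sequence, structure)
    return encode_symbols(symbols)


def decode_steps(steps: Sequence[int]) -> List[CharacteristicSymbol]:
    """Invert a step sequence to characteristic symbols (exact, by bijectivity)."""
    steps = list(steps)
    if len(steps) % 3:
        raise ValidationError("step count must be a multiple of 3")
    out: List[CharacteristicSymbol] = []
    for k in range(0, len(steps), 3):
        triple = tuple(int(s) for s in steps[k : k + 3])
        try:
            out.append(STEPS_TO_SYMBOL[triple])
        except KeyError:
            raise ValidationError(f"invalid step triple {triple}") from None
    return out
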