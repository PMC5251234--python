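"""Domain types for RNA records and dot-bracket secondary structures.

An :class:`RnaRecord` holds one RNA sequence (alphabet ``ACGU``; ``T`` in the
input is silently normalized to ``U`` so DNA-alphabet files are tolerated)
together with an optional secondary structure in dot-bracket notation.
Coordinates are 1-based and inclusive everywhere in user-facing output,
matching the biological convention for point mutations and base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Optional, Tuple

from .errors import ValidationError

RNA_ALPHABET = "ACGU"

#: Minimum sequence length accepted by the top-level comparison, mutation and
#: phylogeny entry points. Encoding primitives themselves work on any length.
MIN_SEQUENCE_LENGTH = 10

_SEQ_TRANSLATION = str.maketrans("acgutT", "ACGUUU")


def normalize_sequence(seq: str) -> str:
    """Uppercase a raw sequence and map T to U; reject other characters."""
    norm = seq.translate(_SEQ_TRANSLATION)
    bad = set(norm) - set(RNA_ALPHABET)
    if bad:
        raise ValidationError(
            f"sequence contains characters outside ACGU/T: {sorted(bad)!r}"
        )
    return norm


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) secondary structure.

    Attributes
    ----------
    dotbracket:
        The structure string over ``.``, ``(`` and ``)``.
    pairs:
        Base pairs as 1-based ``(i, j)`` tuples with ``i < j``. Each index
        occurs in at most one pair; pairs derived from a single-bracket
        dot-bracket string are necessarily nested.
    """

    dotbracket: str
    pairs: FrozenSet[Tuple[int, int]]

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def paired_positions(self) -> FrozenSet[int]:
        """1-based indices of all paired bases."""
        return frozenset(i for pair in self.pairs for i in pair)


def parse_dotbracket(db: str) -> SecondaryStructure:
    """Parse a dot-bracket string into its set of base pairs.

    Uses the standard stack interpretation: ``(`` opens a pair, the matching
    ``)`` closes it, ``.`` is unpaired. Pairs are 1-based with ``i < j``.

    Raises
    ------
    ValidationError
        If the string is unbalanced (the message reports the first offending
        1-based index) or contains bracket characters of another dialect
        (``[``, ``{`` ... used for pseudoknots, which are unsupported).
    """
    stack: list[int] = []
    pairs: set[Tuple[int, int]] = set()
    for idx, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValidationError(
                    f"unbalanced dot-bracket: unmatched ')' at position {idx}"
                )
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            if ch in "[]{}<>":
                raise ValidationError(
                    f"unsupported pseudoknot bracket {ch!r} at position {idx}; "
                    "only the single-bracket dialect '.()' is accepted"
                )
            raise ValidationError(
                f"invalid structure character {ch!r} at position {idx}"
            )
    if stack:
        raise ValidationError(
            f"unbalanced dot-bracket: unmatched '(' at position {stack[0]}"
        )
    return SecondaryStructure(dotbracket=db, pairs=frozenset(pairs))


def pairs_to_dotbracket(pairs, length: int) -> str:
    """Render a set of 1-based nested pairs back to a dot-bracket string."""
    chars = ["."] * length
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


@dataclass(frozen=True)
class RnaRecord:
    """One RNA sequence with an identifier and optional dot-bracket structure.

    The sequence is normalized on construction (uppercase, T mapped to U).
    If a structure is present its length must equal the sequence length and
    it must be balanced.
    """

    id: str
    sequence: str
    structure: Optional[str] = None
    _parsed_structure: Optional[SecondaryStructure] = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        try:
            norm = normalize_sequence(self.sequence)
        except ValidationError as exc:
            raise ValidationError(f"record {self.id!r}: {exc}") from None
        object.__setattr__(self, "sequence", norm)
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValidationError(
                    f"record {self.id!r}: structure length "
                    f"{len(self.structure)} != sequence length {len(self.sequence)}"
                )
            try:
                parsed = parse_dotbracket(self.structure)
            except ValidationError as exc:
                raise ValidationError(f"record {self.id!r}: {exc}") from None
            object.__setattr__(self, "_parsed_structure", parsed)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def secondary_structure(self) -> Optional[SecondaryStructure]:
        """The parsed structure, or None if no structure is attached."""
        return self._parsed_structure

    def with_structure(self, dotbracket: str) -> "RnaRecord":
        """Return a copy of this record carrying the given structure."""
        return replace(self, structure=dotbracket)


def validate_record(rec: RnaRecord, min_len: int = MIN_SEQUENCE_LENGTH) -> RnaRecord:
    """Check a record against the entry-point constraints and return it.

    Sequence length must be at least ``min_len`` (default 10, the minimum
    accepted by all comparison, mutation and phylogeny entry points).
    Structure consistency is already enforced at construction.
    """
    if len(rec) < min_len:
        raise ValidationError(
            f"record {rec.id!r}: sequence length {len(rec)} is below the "
            f"minimum of {min_len}"
        )
    return rec
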