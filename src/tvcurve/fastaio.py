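"""Reader/writer for FASTA and the structure-extended FASTA dialect.

The extended dialect augments plain FASTA with one extra line per record
consisting only of dot-bracket characters, optionally followed by a trailing
parenthesized free-energy annotation in the style RNAfold prints
(``(((...)))  (-1.20)``); the annotation is stripped. Sequence blocks may
span multiple lines and blank lines are ignored. A plain FASTA parser cannot
carry the structure line, hence the dedicated reader here.
"""

from __future__ import annotations

import re
from typing import List, Optional

from .errors import ParseError
from .records import RnaRecord

_ENERGY_RE = re.compile(r"\s*\(\s*-?\d+(?:\.\d+)?\s*\)\s*$")
_STRUCTURE_RE = re.compile(r"^[.()]+$")


def _strip_energy(line: str) -> str:
    return _ENERGY_RE.sub("", line)


def _is_structure_line(line: str) -> bool:
    return bool(_STRUCTURE_RE.match(_strip_energy(line)))


def parse_fasta(text: str) -> List[RnaRecord]:
    """Parse FASTA / extended-FASTA text into a list of records.

    Record order is preserved. A line following the sequence block that
    consists only of ``.()`` characters (after stripping a trailing
    energy annotation) is attached as the record's structure.

    Raises
    ------
    ParseError
        If the text is empty or sequence data precedes the first header;
        the message names the offending line number.
    ValidationError
        Propagated from record construction (bad characters, structure
        length mismatch), naming the record id.
    """
    if not text.strip():
        raise ParseError("empty input: no FASTA records found")

    records: List[RnaRecord] = []
    header: Optional[str] = None
    seq_parts: List[str] = []
    struct_parts: List[str] = []

    def flush() -> None:
        nonlocal header, seq_parts, struct_parts
        if header is None:
            return
        if not seq_parts:
            raise ParseError(f"record {header!r} has no sequence lines")
        structure = "".join(struct_parts) if struct_parts else None
        records.append(
            RnaRecord(id=header, sequence="".join(seq_parts), structure=structure)
        )
        header, seq_parts, struct_parts = None, [], []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise ParseError(f"malformed header at line {lineno}: empty id")
            header = name.split()[0]
        elif header is None:
            raise ParseError(
                f"line {lineno}: sequence data before the first '>' header"
            )
        elif _is_structure_line(line):
            struct_parts.append(_strip_energy(line))
        else:
            if struct_parts:
                raise ParseError(
                    f"line {lineno}: sequence line after a structure line in "
                    f"record {header!r}"
                )
            seq_parts.append(line)
    flush()

    if not records:
        raise ParseError("no FASTA records found in input")
    return records


def write_fasta(records, include_structures: bool = True) -> str:
    """Serialize records to the extended-FASTA dialect (round-trip safe)."""
    lines: List[str] = []
    for rec in records:
        lines.append(f">{rec.id}")
        lines.append(rec.sequence)
        if include_structures and rec.structure is not None:
            lines.append(rec.structure)
    return "\n".join(lines) + "\n"


def read_fasta_file(path) -> List[RnaRecord]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_fasta(fh.read())


def write_fasta_file(path, records, include_structures: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_fasta(records, include_structures=include_structures))
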