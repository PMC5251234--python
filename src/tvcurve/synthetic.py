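"""Synthetic RNA family generator used throughout the test surface.

Each family starts from a random ancestor sequence; members are derived by
independent per-site substitutions at a fixed mutation rate and every
sequence (ancestor and members) is folded with the deterministic built-in
backend, so generated records carry structures. The defaults — 4 families
of 20 members, length 60, substitution rate 0.05 — are the planted-family
conditions exercised by the family-recovery analyses: close enough within a
family that curves stay similar, far enough between families that the tree
should separate them.

All randomness flows through one seeded generator, so a fixed seed yields a
byte-identical record set.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .folding import FoldingBackend, NussinovBackend
from .records import RNA_ALPHABET, RnaRecord

_BASES = np.array(list(RNA_ALPHABET))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each site with probability ``rate``.

    A substituted site always changes (one of the three other bases,
    uniformly), so the expected Hamming distance is rate * len(seq).
    """
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in RNA_ALPHABET if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_families(
    n_families: int = 4,
    members: int = 20,
    length: int = 60,
    mutation_rate: float = 0.05,
    seed: int = 0,
    backend: Optional[FoldingBackend] = None,
) -> List[RnaRecord]:
    """Planted RNA families: records labelled ``family{i}_member{j}`` (1-based).

    Each member is an independently mutated copy of its family's random
    ancestor, re-folded so its structure reflects its own sequence.
    """
    if n_families < 1 or members < 1 or length < 1:
        raise ValueError("family count, members and length must be positive")
    if not 0.0 < mutation_rate < 1.0:
        raise ValueError("mutation_rate must lie in (0, 1)")
    backend = backend or NussinovBackend()
    rng = np.random.default_rng(seed)
    records: List[RnaRecord] = []
    for fam in range(1, n_families + 1):
        ancestor = random_sequence(length, rng)
        for mem in range(1, members + 1):
            seq = mutate_sequence(ancestor, mutation_rate, rng)
            records.append(
                RnaRecord(
                    id=f"family{fam}_member{mem}",
                    sequence=seq,
                    structure=backend.fold(seq),
                )
            )
    return records


def planted_family_labels(records) -> List[str]:
    """Family part of each generated record id (ground truth for recovery)."""
    return [rec.id.split("_")[0] for rec in records]
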