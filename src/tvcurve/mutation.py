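"""Single-point structural mutation scanning.

Every position of an RNA of length N admits three substitutions, giving 3N
single-point mutants. Each mutant is re-folded with the same backend as the
wild type (mutants never inherit the wild-type structure: a substitution can
rearrange the optimal pairing), encoded as a TV-curve, and scored by the
structural distance 1 - multiscale similarity to the wild type. The scan
reports the full ranked mutant table, the per-position deleteriousness
profile (the maximum distance among the three substitutions at each
position — peaks mark structurally critical sites), a histogram of all 3N
distances summarizing mutational robustness, and the single maximal mutant.

Ties for the maximal mutant are broken by lowest position, then by
substitution in A < C < G < U order, so reports are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .encoding import TVCurve, encode_tvcurve
from .folding import FoldingBackend, ensure_structure
from .records import RNA_ALPHABET, RnaRecord, validate_record
from .similarity import SimilarityConfig, multiscale_similarity, similarity_to_distance

_BASE_RANK = {b: i for i, b in enumerate(RNA_ALPHABET)}


@dataclass(frozen=True)
class MutationRecord:
    """One single-point mutant and its structural distance to the wild type."""

    position: int  # 1-based
    from_base: str
    to_base: str
    mutant_structure: str
    distance: float


@dataclass(frozen=True)
class MutationScanResult:
    """Complete output of a single-point mutation scan."""

    wild_type: RnaRecord
    wild_curve: TVCurve
    mutants: List[MutationRecord]  # ranked by distance descending
    profile: np.ndarray  # per-position maximum distance, length N
    profile_argmax: List[MutationRecord]  # the maximal mutant per position
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray

    @property
    def maximal_mutant(self) -> MutationRecord:
        """The mutant with the largest structural distance (fixed tie-break)."""
        return self.mutants[0]

    def mutants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [m.position for m in self.mutants],
                "from": [m.from_base for m in self.mutants],
                "to": [m.to_base for m in self.mutants],
                "distance": [m.distance for m in self.mutants],
                "structure": [m.mutant_structure for m in self.mutants],
            }
        )

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.profile) + 1),
                "max_distance": self.profile,
                "from": [m.from_base for m in self.profile_argmax],
                "to": [m.to_base for m in self.profile_argmax],
            }
        )

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.histogram_edges[:-1],
                "bin_high": self.histogram_edges[1:],
                "count": self.histogram_counts,
            }
        )


def enumerate_mutants(seq: str) -> List[Tuple[int, str, str, str]]:
    """All 3N single-point mutants of ``seq``.

    Returns ``(position, from_base, to_base, mutant_sequence)`` tuples,
    ordered by position ascending then substitution in A < C < G < U order.
    """
    out: List[Tuple[int, str, str, str]] = []
    for i, base in enumerate(seq):
        for sub in RNA_ALPHABET:
            if sub == base:
                continue
            out.append((i + 1, base, sub, seq[:i] + sub + seq[i + 1 :]))
    return out


def distance_histogram(
    distances: np.ndarray, bins: int = 20
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform-bin histogram of mutant distances over [0, max(distance, eps)].

    Counts always sum to the number of distances; the epsilon floor keeps
    the bin width positive when every mutant is structurally neutral.
    """
    distances = np.asarray(distances, dtype=float)
    upper = max(float(distances.max(initial=0.0)), 1e-9)
    counts, edges = np.histogram(distances, bins=bins, range=(0.0, upper))
    return edges, counts


def scan_mutations(
    rec: RnaRecord,
    backend: FoldingBackend,
    cfg: Optional[SimilarityConfig] = None,
    bins: int = 20,
) -> MutationScanResult:
    """Fold and score every single-point mutant of one RNA record.

    The wild-type structure is predicted first if the record does not carry
    one, then held fixed for the whole scan.
    """
    cfg = cfg or SimilarityConfig()
    rec = validate_record(rec)
    rec = ensure_structure(rec, backend)
    wild_curve = encode_tvcurve(rec)

    records: List[MutationRecord] = []
    for pos, from_base, to_base, mut_seq in enumerate_mutants(rec.sequence):
        structure = backend.fold(mut_seq)
        mut_curve = encode_tvcurve(
            RnaRecord(id=f"{rec.id}_{from_base}{pos}{to_base}", sequence=mut_seq,
                      structure=structure)
        )
        dist = similarity_to_distance(multiscale_similarity(wild_curve, mut_curve, cfg))
        records.append(
            MutationRecord(
                position=pos,
                from_base=from_base,
                to_base=to_base,
                mutant_structure=structure,
                distance=dist,
            )
        )

    n = len(rec)
    profile = np.zeros(n)
    argmax: List[Optional[MutationRecord]] = [None] * n
    for m in records:
        i = m.position - 1
        if argmax[i] is None or m.distance > profile[i]:
            profile[i] = m.distance
            argmax[i] = m

    ranked = sorted(
        records,
        key=lambda m: (-m.distance, m.position, _BASE_RANK[m.to_base]),
    )
    edges, counts = distance_histogram(
        np.array([m.distance for m in records]), bins=bins
    )
    return MutationScanResult(
        wild_type=rec,
        wild_curve=wild_curve,
        mutants=ranked,
        profile=profile,
        profile_argmax=[m for m in argmax if m is not None],
        histogram_edges=edges,
        histogram_counts=counts,
    )
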