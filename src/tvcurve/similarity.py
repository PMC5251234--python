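"""Wavelet multi-scale similarity between two TV-curves.

Two curves are compared by (1) extracting a numeric signal from each (the
cumulative curve ordinates by default, or the raw +/-1 step signal),
(2) linearly resampling both to a common dyadic length — the smallest power
of two at least as long as the longer signal, so an exact L-level pyramid
runs with no boundary padding, (3) running an L-level discrete wavelet
decomposition of each (Haar by default: natural for +/-1 step signals and
exactly dyadic), and (4) taking a weighted sum of the Pearson correlations
between the two signals' coefficient vectors at each level — the
approximation plus the L detail levels, uniform weights 1/(L+1) by default.
The approximation correlation captures the coarse, global shape of the
curves, the fine detail levels capture local structure, so the weighted sum
is sensitive to both. The score lies in [-1, 1]; distance = 1 - score.

Zero-variance convention: the Pearson correlation is undefined for a
constant vector, so if at some level both coefficient vectors are constant
and identical the level contributes 1, and if one or both are constant
otherwise it contributes 0. (Length-one vectors, e.g. the approximation at
full depth, are constant by definition.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pywt

from .encoding import TVCurve

logger = logging.getLogger(__name__)


@dataclass
class SimilarityConfig:
    """Configuration of the multi-scale similarity.

    Parameters
    ----------
    levels:
        Decomposition depth L (default 4).
    wavelet:
        Wavelet family name as understood by PyWavelets (default "haar").
    weights:
        Optional L+1 nonnegative level weights, ordered approximation first,
        then details fine-to-coarse d_1..d_L. Normalized to sum to 1; by
        default uniform 1/(L+1).
    signal_kind:
        "cumulative" (the curve ordinates, default) or "steps" (the raw
        +/-1 signal).
    """

    levels: int = 4
    wavelet: str = "haar"
    weights: Optional[Sequence[float]] = None
    signal_kind: str = "cumulative"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.signal_kind not in ("cumulative", "steps"):
            raise ValueError(f"unknown signal kind {self.signal_kind!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.levels + 1,):
                raise ValueError(
                    f"expected {self.levels + 1} weights (approximation + "
                    f"{self.levels} detail levels), got {w.shape}"
                )
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")

    def normalized_weights(self, levels: Optional[int] = None) -> np.ndarray:
        """Level weights summing to 1 (approximation first, then d_1..d_L)."""
        L = self.levels if levels is None else levels
        if self.weights is None:
            return np.full(L + 1, 1.0 / (L + 1))
        w = np.asarray(self.weights, dtype=float)[: L + 1]
        return w / w.sum()


@dataclass(frozen=True)
class WaveletDecomposition:
    """Multilevel wavelet coefficients of one signal.

    ``details[j-1]`` holds the level-j detail vector d_j, finest first; for
    the Haar family on a dyadic-length signal |d_j| = len/2^j and
    |approx| = len/2^L.
    """

    approx: np.ndarray
    details: List[np.ndarray]
    levels: int
    wavelet: str
    length: int = field(default=0)

    def reconstruct(self) -> np.ndarray:
        """Invert the transform (exact up to floating round-off)."""
        coeffs = [self.approx] + list(reversed(self.details))
        return pywt.waverec(coeffs, self.wavelet, mode="periodization")[
            : self.length or None
        ]


def resample_signal(signal: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly interpolate a signal onto ``target_len`` uniform points.

    Both the input samples and the output grid are viewed as uniform on
    [0, 1]; endpoints are preserved exactly.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2 or target_len < 2:
        raise ValueError("resampling requires input and output lengths >= 2")
    if signal.size == target_len:
        return signal.copy()
    src = np.linspace(0.0, 1.0, signal.size)
    dst = np.linspace(0.0, 1.0, target_len)
    return np.interp(dst, src, signal)


def wavelet_decompose(
    signal: np.ndarray, cfg: SimilarityConfig
) -> WaveletDecomposition:
    """L-level discrete wavelet decomposition (periodized, orthonormal).

    If the requested depth exceeds what the signal length supports, the
    depth is reduced to floor(log2(len)) with a logged warning.
    """
    signal = np.asarray(signal, dtype=float)
    max_level = int(math.floor(math.log2(signal.size))) if signal.size > 1 else 0
    level = cfg.levels
    if level > max_level:
        logger.warning(
            "decomposition level %d too deep for signal length %d; using %d",
            level,
            signal.size,
            max_level,
        )
        level = max_level
    coeffs = pywt.wavedec(signal, cfg.wavelet, mode="periodization", level=level)
    return WaveletDecomposition(
        approx=coeffs[0],
        details=list(reversed(coeffs[1:])),
        levels=level,
        wavelet=cfg.wavelet,
        length=signal.size,
    )


def _level_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.array_equal(u, v):  # keeps sim(A, A) exactly 1
        return 1.0
    u_const = np.all(u == u[0])
    v_const = np.all(v == v[0])
    if u_const or v_const:
        return 1.0 if (u_const and v_const and np.array_equal(u, v)) else 0.0
    if v.tobytes() < u.tobytes():  # fix operand order so sim(A,B) == sim(B,A) bitwise
        u, v = v, u
    return float(np.corrcoef(u, v)[0, 1])


def _common_dyadic_length(n_a: int, n_b: int) -> int:
    longest = max(n_a, n_b)
    return 1 << max(1, math.ceil(math.log2(longest)))


def multiscale_similarity(
    a: TVCurve, b: TVCurve, cfg: Optional[SimilarityConfig] = None
) -> float:
    """The weighted multi-scale Pearson similarity of two TV-curves.

    Returns a score in [-1, 1]; 1 for identical curves. Symmetric in its
    arguments by construction.
    """
    cfg = cfg or SimilarityConfig()
    sig_a = a.signal(cfg.signal_kind)
    sig_b = b.signal(cfg.signal_kind)
    target = _common_dyadic_length(sig_a.size, sig_b.size)
    sig_a = resample_signal(sig_a, target)
    sig_b = resample_signal(sig_b, target)
    dec_a = wavelet_decompose(sig_a, cfg)
    dec_b = wavelet_decompose(sig_b, cfg)
    levels = min(dec_a.levels, dec_b.levels)
    weights = cfg.normalized_weights(levels)
    corr = [_level_correlation(dec_a.approx, dec_b.approx)]
    corr.extend(
        _level_correlation(dec_a.details[j], dec_b.details[j]) for j in range(levels)
    )
    # fsum keeps sim(A, A) exactly 1 under uniform weights
    return float(math.fsum(w * c for w, c in zip(weights, corr)))


def similarity_to_distance(score: float) -> float:
    """Structural distance = 1 - similarity; 0 for identical curves, max 2."""
    return 1.0 - score


def tvcurve_distance(
    a: TVCurve, b: TVCurve, cfg: Optional[SimilarityConfig] = None
) -> float:
    """Convenience: 1 - multiscale_similarity(a, b, cfg)."""
    return similarity_to_distance(multiscale_similarity(a, b, cfg))
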