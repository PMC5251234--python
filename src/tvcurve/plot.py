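"""Optional matplotlib exports of curves, profiles and histograms.

Imported lazily; matplotlib is an optional dependency (``pip install
tvcurve[plot]``). Aesthetics are deliberately minimal — these are
diagnostic plots, not figures.
"""

from __future__ import annotations

import numpy as np

from .encoding import TVCurve
from .mutation import MutationScanResult


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    return fig, ax


def plot_curve(curve: TVCurve, path, title: str = "") -> None:
    """Line plot of the 3N+1 cumulative curve points."""
    fig, ax = _axes()
    pts = curve.points
    ax.plot(pts[:, 0], pts[:, 1], lw=0.8)
    ax.set_xlabel("step index")
    ax.set_ylabel("cumulative ordinate")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_profile(result: MutationScanResult, path) -> None:
    """Per-position deleteriousness profile of a mutation scan."""
    fig, ax = _axes()
    pos = np.arange(1, len(result.profile) + 1)
    ax.bar(pos, result.profile, width=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel("max structural distance")
    ax.set_title(f"deleteriousness profile: {result.wild_type.id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_histogram(result: MutationScanResult, path) -> None:
    """Distance distribution over all 3N single-point mutants."""
    fig, ax = _axes()
    widths = np.diff(result.histogram_edges)
    ax.bar(result.histogram_edges[:-1], result.histogram_counts,
           width=widths, align="edge")
    ax.set_xlabel("structural distance to wild type")
    ax.set_ylabel("mutant count")
    ax.set_title(f"mutant distances: {result.wild_type.id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
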