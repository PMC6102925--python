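"""Per-sample repeat-size populations and assay-unit conversions.

The expanded-allele population is summarized by a Gaussian kernel
density estimate (Silverman bandwidth): its local maxima are the
distribution's modes, and "pdf percentiles" are quantiles of the KDE
restricted to the expanded class. Conversions between assay units
(Southern-blot kb, fragment-analysis bp) and repeat counts subtract a
fixed flanking-sequence contribution before dividing by the motif
length; the shipped flank constants are documented defaults for the
C9orf72 GGGGCC assay designs and are always overridable.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .anchor import CLASS_EXPANDED, STATUS_SPANNING, RepeatCall

__all__ = [
    "AlleleDistribution",
    "summarize",
    "southern_to_repeats",
    "fragment_to_repeats",
    "repeats_to_fragment",
    "plot_distribution",
    "SOUTHERN_FLANK_BP",
    "FRAGMENT_FLANK_BP",
]

# Flanking-sequence contributions for the C9orf72 G4C2 assay designs:
# restriction fragment (Southern) and fluorescent-PCR amplicon (fragment
# analysis). Derived once from the locus geometry; user-overridable.
SOUTHERN_FLANK_BP = 2302
FRAGMENT_FLANK_BP = 117

DEFAULT_PERCENTILES = (0.975, 0.99)
MODE_PROMINENCE_FLOOR = 0.05
_GRID_POINTS = 4096


@dataclass
class AlleleDistribution:
    """Summary of a per-sample repeat-unit population."""

    unit_counts: np.ndarray  # repeat_units of all spanning calls
    class_tally: dict[str, int]
    modes: list[float]  # expanded-class KDE modes, ascending
    pdf_percentiles: dict[float, int]  # percentile -> repeat units
    flags: tuple[str, ...] = ()
    n_spanning: int = 0
    n_expanded: int = 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(
    calls: Iterable[RepeatCall],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    mode_floor: float = MODE_PROMINENCE_FLOOR,
) -> AlleleDistribution:
    """Histogram, expanded-class KDE modes and density percentiles.

    Requires at least one spanning call. Modes are local maxima of the
    expanded-class KDE whose density exceeds ``mode_floor`` of the global
    maximum (suppresses noise modes). With no expanded calls the modes
    and percentiles are empty and the result is flagged.
    """
    spanning = sorted(
        (c for c in calls if c.status == STATUS_SPANNING),
        key=lambda c: (c.read_id, c.repeat_units),
    )
    if not spanning:
        raise ValueError("summarize requires at least one spanning call")
    units = np.array([c.repeat_units for c in spanning], dtype=float)
    tally = dict(Counter(c.allele_class for c in spanning))
    expanded = np.array(
        [c.repeat_units for c in spanning if c.allele_class == CLASS_EXPANDED],
        dtype=float,
    )
    flags: list[str] = []
    modes: list[float] = []
    pcts: dict[float, int] = {}
    if expanded.size == 0:
        flags.append("no_expanded_calls")
    elif np.ptp(expanded) == 0.0:
        value = float(expanded[0])
        modes = [value]
        pcts = {float(p): _round_half_up(value) for p in percentiles}
        flags.append("degenerate_expanded_distribution")
    else:
        kde = gaussian_kde(expanded, bw_method="silverman")
        bw = float(kde.factor * expanded.std(ddof=1))
        lo = expanded.min() - 3 * bw
        hi = expanded.max() + 3 * bw
        grid = np.linspace(lo, hi, _GRID_POINTS)
        density = kde(grid)
        peak = density.max()
        interior = density[1:-1]
        is_max = (interior >= density[:-2]) & (interior > density[2:])
        keep = is_max & (interior >= mode_floor * peak)
        modes = [float(grid[i + 1]) for i in np.flatnonzero(keep)]
        cdf = np.concatenate([[0.0], np.cumsum((density[1:] + density[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        for p in percentiles:
            idx = int(np.searchsorted(cdf, float(p), side="left"))
            idx = min(idx, grid.size - 1)
            pcts[float(p)] = _round_half_up(float(grid[idx]))
    return AlleleDistribution(
        unit_counts=units.astype(int),
        class_tally=tally,
        modes=modes,
        pdf_percentiles=pcts,
        flags=tuple(flags),
        n_spanning=len(spanning),
        n_expanded=int(expanded.size),
    )


def southern_to_repeats(
    band_kb: float,
    flank_bp: int = SOUTHERN_FLANK_BP,
    motif_len: int = 6,
) -> int:
    """Southern-blot band size (kb, flanks included) -> repeat units."""
    band_bp = band_kb * 1000.0
    if band_bp < flank_bp:
        raise ValueError(
            f"band ({band_bp:.0f} bp) smaller than flanking contribution ({flank_bp} bp)"
        )
    return _round_half_up((band_bp - flank_bp) / motif_len)


def fragment_to_repeats(
    peak_bp: float,
    flank_bp: int = FRAGMENT_FLANK_BP,
    motif_len: int = 6,
) -> int:
    """Fragment-analysis peak (bp) -> repeat units; warns if far from integral."""
    if peak_bp < flank_bp:
        raise ValueError(
            f"peak ({peak_bp} bp) smaller than flanking contribution ({flank_bp} bp)"
        )
    exact = (peak_bp - flank_bp) / motif_len
    units = _round_half_up(exact)
    if abs(exact - units) > 0.25:
        warnings.warn(
            f"peak {peak_bp} bp is {exact:.2f} units; not close to an integral "
            "repeat count — check the flank constant",
            stacklevel=2,
        )
    return units


def repeats_to_fragment(
    units: int,
    flank_bp: int = FRAGMENT_FLANK_BP,
    motif_len: int = 6,
) -> int:
    """Exact inverse of :func:`fragment_to_repeats` on integral units."""
    if units < 0:
        raise ValueError("units must be non-negative")
    return units * motif_len + flank_bp


def plot_distribution(dist: AlleleDistribution, path: str) -> None:
    """Histogram of spanning repeat units with expanded-class KDE overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(dist.unit_counts, bins=60, color="#4878a8", alpha=0.8)
    for mode in dist.modes:
        ax.axvline(mode, color="firebrick", linestyle="--", linewidth=1)
    ax.set_xlabel("repeat units")
    ax.set_ylabel("spanning reads")
    ax.set_title("Repeat-unit distribution (modes dashed)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
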