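"""TEM-derived magnetosome statistics.

Particle diameters arrive as long-format tables (condition, replicate,
timepoint, diameter in nm) with a companion per-cell table (cell length in
um, magnetosome count).  Triplicates of ~1000 particles are pooled before
summary; between-condition size comparisons use the Wilcoxon rank-sum test
(exact enumeration with midranks for small samples, tie- and continuity-
corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParticleDataset",
    "SizeSummary",
    "pool_triplicates",
    "summarize_sizes",
    "per_cell_density",
    "wilcoxon_rank_sum",
    "violin_box_plot",
]

PARTICLE_COLUMNS = ["condition", "replicate", "timepoint_h", "diameter_nm"]
CELL_COLUMNS = ["condition", "replicate", "timepoint_h", "cell_id", "length_um", "ms_count"]


@dataclass
class ParticleDataset:
    """Per-particle diameters plus a companion per-cell table."""

    particles: pd.DataFrame
    cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CELL_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in PARTICLE_COLUMNS if c not in self.particles.columns]
        if missing:
            raise ValueError(f"particle table is missing columns: {missing}")
        d = self.particles["diameter_nm"]
        if len(d) and (d <= 0).any():
            row = int(self.particles.index[d <= 0][0])
            raise ValueError(f"non-positive diameter at row {row}")
        if len(self.particles) and (self.particles["timepoint_h"] < 0).any():
            raise ValueError("timepoints must be non-negative")

    @property
    def n(self) -> int:
        return len(self.particles)


@dataclass
class SizeSummary:
    n: int
    mean: float          # nm
    sd: float            # nm, sample sd (n-1)
    median: float        # nm
    iqr: float           # nm
    fraction_above_30nm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_above_30nm <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


def pool_triplicates(
    dataset: ParticleDataset, condition: str, timepoint: float
) -> ParticleDataset:
    """Combine replicate counts for one condition/timepoint (provenance kept)."""
    p = dataset.particles
    mask = (p["condition"] == condition) & np.isclose(p["timepoint_h"], timepoint)
    if not mask.any():
        keys = sorted(
            {(c, float(t)) for c, t in zip(p["condition"], p["timepoint_h"])}
        )
        raise KeyError(
            f"no particles for ({condition!r}, {timepoint}); available: {keys}"
        )
    c = dataset.cells
    cmask = (
        (c["condition"] == condition) & np.isclose(c["timepoint_h"], timepoint)
        if len(c)
        else slice(0, 0)
    )
    return ParticleDataset(
        p[mask].reset_index(drop=True),
        c[cmask].reset_index(drop=True) if len(c) else c,
    )


def summarize_sizes(diameters: np.ndarray, threshold: float = 30.0) -> SizeSummary:
    """Pooled size statistics; the exceedance fraction is strict (> threshold)."""
    d = np.asarray(diameters, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two diameters")
    if (d <= 0).any():
        row = int(np.nonzero(d <= 0)[0][0])
        raise ValueError(f"non-positive diameter at row {row}")
    q75, q25 = np.percentile(d, [75, 25])
    return SizeSummary(
        n=len(d),
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)),
        median=float(np.median(d)),
        iqr=float(q75 - q25),
        fraction_above_30nm=float(np.mean(d > threshold)),
    )


def per_cell_density(cells: pd.DataFrame) -> dict:
    """Magnetosomes per cell and per um of cell length (mean +/- sd over cells).

    Computed as the mean of per-cell ratios, not the ratio of means, matching
    how per-cell normalized counts are tabulated.
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    lengths = cells["length_um"].to_numpy(dtype=float)
    counts = cells["ms_count"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero or negative cell length present")
    ratio = counts / lengths
    def _ms(x):
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return {
        "ms_per_cell": _ms(counts),
        "ms_per_um": _ms(ratio),
        "n_cells": len(cells),
    }


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(
    a: np.ndarray, b: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic W_a, p).

    ``mode``: ``"exact"`` enumerates all C(n, n_a) rank assignments (midranks
    for ties; only feasible for n_a + n_b <= 12), ``"normal"`` uses the
    tie-corrected normal approximation with continuity correction, ``"auto"``
    picks exact for small samples.  Two-sided exact p doubles the smaller
    tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = _midranks(np.concatenate([a, b]))
    w = float(np.sum(ranks[:n_a]))

    if mode == "auto":
        mode = "exact" if n <= 12 else "normal"
    if mode == "exact":
        if n > 12:
            raise ValueError(
                f"exact enumeration limited to n_a + n_b <= 12 (got {n}); "
                "use mode='normal'"
            )
        sums = np.array([
            sum(combo) for combo in itertools.combinations(ranks, n_a)
        ])
        total = len(sums)
        p_low = np.sum(sums <= w + 1e-12) / total
        p_high = np.sum(sums >= w - 1e-12) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w, p
    if mode not in ("normal", "normal-approximation"):
        raise ValueError(f"unknown mode {mode!r}")

    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n_a * n_b * (n + 1) / 12.0 - n_a * n_b * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return w, 1.0  # all observations tied
    diff = w - mean
    z = (abs(diff) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return w, p


def violin_box_plot(groups: dict, ax=None, threshold: float | None = 30.0):
    """Violin + box plot of diameter groups, whiskers at the 5th/95th pct.

    ``groups`` maps label -> array of diameters.  Points beyond the 5th/95th
    percentiles are drawn individually; the red dot marks the mean.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * max(len(groups), 2), 4))
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    ax.violinplot(data, showextrema=False)
    ax.boxplot(
        data,
        whis=(5, 95),
        showfliers=True,
        flierprops=dict(marker=".", markerfacecolor="grey", markeredgecolor="grey"),
        medianprops=dict(color="black"),
    )
    for i, d in enumerate(data, start=1):
        ax.plot(i, np.mean(d), "o", color="red", ms=4, zorder=5)
    if threshold is not None:
        ax.axhline(threshold, ls="--", lw=0.8, color="0.4")
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("magnetosome diameter (nm)")
    return ax
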