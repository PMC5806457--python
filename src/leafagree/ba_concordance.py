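"""Modified Bland-Altman concordance for discrete counts.

In a classical BA scatter of integer counts, coincident points overplot and
misrepresent the distribution.  Here coincident (pair mean, difference)
coordinates are merged into multiplicity-weighted cells; a figure layer can
render them as colour-coded squares, but all statistics (bias and 1.96-SD
limits of agreement) live in :class:`BAGrid` so nothing needs to inspect
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import PairedCounts
from .errors import InsufficientDataError


@dataclass
class BAGrid:
    """Merged BA cells with bias and limits of agreement.

    ``cells`` has columns (mean_value, diff_value, multiplicity); the
    multiplicities sum to the number of pairs.  ``loa_low``/``loa_high``
    are ``bias -/+ 1.96 * sd(diffs)`` with the sample (n-1) SD.
    """

    cells: pd.DataFrame
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def ba_grid(paired: PairedCounts) -> BAGrid:
    """Build the multiplicity-merged Bland-Altman grid for a count pair."""
    if paired.n < 2:
        raise InsufficientDataError("need at least 2 pairs for a BA grid")
    diffs = paired.diffs.astype(float)
    means = (paired.x_ref + paired.x_other) / 2.0
    cells = (
        pd.DataFrame({"mean_value": means, "diff_value": diffs})
        .groupby(["mean_value", "diff_value"], sort=True)
        .size()
        .rename("multiplicity")
        .reset_index()
    )
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BAGrid(
        cells=cells,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=paired.n,
    )


def diff_histogram(paired: PairedCounts) -> dict:
    """Histogram of count differences, ``difference -> occurrences``."""
    if paired.n < 1:
        raise InsufficientDataError("need at least 1 pair")
    diffs = paired.diffs
    values, counts = np.unique(diffs, return_counts=True)
    out = {}
    for v, c in zip(values, counts):
        key = int(v) if float(v).is_integer() else float(v)
        out[key] = int(c)
    return out


def plot_ba_grid(grid: BAGrid, path=None, ax=None, cmap: str = "viridis"):
    """Render a BA grid as colour-coded squares (optional figure layer)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(
        grid.cells["mean_value"],
        grid.cells["diff_value"],
        c=grid.cells["multiplicity"],
        cmap=cmap,
        marker="s",
        s=60,
    )
    for y, style in ((grid.bias, "-"), (grid.loa_low, "--"), (grid.loa_high, "--")):
        ax.axhline(y, color="grey", linestyle=style, linewidth=1)
    ax.set_xlabel("pair mean count")
    ax.set_ylabel("count difference (reference - other)")
    ax.figure.colorbar(sc, ax=ax, label="multiplicity")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_diff_histogram(paired: PairedCounts, path=None, ax=None):
    """Bar chart of the integer difference histogram."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    hist = diff_histogram(paired)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(list(hist.keys()), list(hist.values()), width=0.8, color="steelblue")
    ax.set_xlabel("count difference")
    ax.set_ylabel("images")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
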