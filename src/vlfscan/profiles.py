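"""Positional VLF summaries: deciles, sliding windows, trim and cutoff sweeps.

Singleton variants concentrate at the 5' and 3' ends of Sanger reads, where
chromatograms deteriorate and coverage drops to a single strand.  These
profiles make that spatial structure visible and quantify how much of it a
given end-trim or cutoff choice would remove.

Everything here is a data product; rendering to PNG/SVG is optional sugar on
top (:func:`render_plots`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import VlfResult, vlf_analysis
from .seqtable import SequenceTable


@dataclass
class DecileProfile:
    """VLF counts in each tenth of the alignment: (singleton, shared, total) x 10."""

    bins: np.ndarray  # (10, 3)

    @property
    def totals(self) -> np.ndarray:
        return self.bins[:, 2]


@dataclass
class WindowProfile:
    """Per-site mean VLF count in windows of ``n`` positions, step 1.

    ``starts[k]`` is the 1-based first position of window k; the three value
    series are singleton, shared and total means (window sum / n).
    """

    n: int
    starts: np.ndarray
    singleton: np.ndarray
    shared: np.ndarray
    total: np.ndarray


@dataclass
class SweepSurface:
    """Grid of VLF totals remaining/removed under trimming or cutoff choices.

    For trim sweeps ``axis1``/``axis2`` are 5'/3' trim amounts and each cell
    holds (remaining singleton, remaining shared, remaining total,
    removed total).  For cutoff sweeps ``axis1`` is the cutoff grid and
    ``axis2`` is empty; cells hold (singleton, shared, total, 0).
    """

    kind: str
    axis1: np.ndarray
    axis2: np.ndarray
    cells: np.ndarray  # (len(axis1), max(len(axis2), 1), 4)


def _decile_bin(position: int, seqlength: int) -> int:
    """0-based decile of a 1-based position, real-valued cut points."""
    return min(9, math.ceil(10 * position / seqlength) - 1)


def decile_profile(result: VlfResult) -> DecileProfile:
    """Aggregate per-position singleton/shared counts into ten bins.

    Bin k (1-based) covers positions i with (k-1)·L/10 < i <= k·L/10; for
    L = 648 the bins alternate between 64 and 65 positions.
    """
    bins = np.zeros((10, 3), dtype=np.int64)
    L = result.seqlength
    for i in range(L):
        b = _decile_bin(i + 1, L)
        bins[b, 0] += result.sas[i, 0]
        bins[b, 1] += result.sas[i, 1]
    bins[:, 2] = bins[:, 0] + bins[:, 1]
    return DecileProfile(bins)


def sliding_window(result: VlfResult, n: int = 30) -> WindowProfile:
    """Moving per-site mean of VLF counts, window ``n``, step 1 bp.

    Start s covers positions s..s+n-1; the value is the window's VLF count
    divided by n, reported separately for singleton and shared classes.
    """
    L = result.seqlength
    if n > L:
        raise ValueError(f"window size {n} exceeds alignment length {L}")
    kernel = np.ones(n)
    single = np.convolve(result.sas[:, 0], kernel, mode="valid") / n
    shared = np.convolve(result.sas[:, 1], kernel, mode="valid") / n
    return WindowProfile(
        n=n,
        starts=np.arange(1, L - n + 2),
        singleton=single,
        shared=shared,
        total=single + shared,
    )


def trim_sweep(
    table: SequenceTable,
    grid5: list[int],
    grid3: list[int],
    p: float = 0.001,
    recompute: bool = False,
) -> SweepSurface:
    """VLF totals after trimming every (5' amount, 3' amount) pair.

    Per-position frequencies do not depend on other columns, so trimming is
    column deletion: remaining totals are the untrimmed per-position tallies
    summed over surviving columns.  ``recompute=True`` instead reruns the
    full analysis on each trimmed table — the slow route exists purely to
    cross-check the identity (it must give identical numbers).
    """
    base = vlf_analysis(table, p=p)
    L = table.seqlength
    cells = np.zeros((len(grid5), len(grid3), 4), dtype=np.int64)
    for a, t5 in enumerate(grid5):
        for b, t3 in enumerate(grid3):
            if t5 < 0 or t3 < 0 or t5 + t3 >= L:
                raise ValueError(f"degenerate trim ({t5}, {t3}) for length {L}")
            if recompute:
                sub = vlf_analysis(table.trim(t5, t3), p=p)
                s, h = sub.n_singleton, sub.n_shared
            else:
                keep = base.sas[t5 : L - t3]
                s, h = int(keep[:, 0].sum()), int(keep[:, 1].sum())
            cells[a, b] = (s, h, s + h, base.total - (s + h))
    return SweepSurface(
        kind="trim",
        axis1=np.asarray(grid5),
        axis2=np.asarray(grid3),
        cells=cells,
    )


def cutoff_sweep(table: SequenceTable, p_grid: list[float]) -> SweepSurface:
    """Singleton/shared/total VLF counts across a grid of cutoff frequencies.

    Flagged sets are nested across p (monotone in the cutoff), so totals are
    non-decreasing along the grid.
    """
    for p in p_grid:
        if not 0.0 < p < 1.0:
            raise ValueError("all cutoffs must lie strictly in (0, 1)")
    cells = np.zeros((len(p_grid), 1, 4), dtype=np.int64)
    for i, p in enumerate(p_grid):
        res = vlf_analysis(table, p=p)
        cells[i, 0] = (res.n_singleton, res.n_shared, res.total, 0)
    return SweepSurface(
        kind="cutoff",
        axis1=np.asarray(p_grid, dtype=float),
        axis2=np.asarray([], dtype=float),
        cells=cells,
    )


def render_plots(profile, out_path) -> None:
    """Render a profile to an image file (stacked bars / lines / heatmap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if isinstance(profile, DecileProfile):
        x = np.arange(1, 11)
        ax.bar(x, profile.bins[:, 0], label="singleton", color="#3465a4")
        ax.bar(
            x,
            profile.bins[:, 1],
            bottom=profile.bins[:, 0],
            label="shared",
            color="#cc0000",
        )
        ax.set_xlabel("decile of alignment")
        ax.set_ylabel("VLF count")
        ax.legend()
    elif isinstance(profile, WindowProfile):
        ax.plot(profile.starts, profile.singleton, label="singleton", color="#3465a4")
        ax.plot(profile.starts, profile.shared, label="shared", color="#cc0000")
        ax.set_xlabel(f"window start (n = {profile.n})")
        ax.set_ylabel("mean VLFs per site")
        ax.legend()
    elif isinstance(profile, SweepSurface):
        if profile.kind == "trim":
            im = ax.imshow(
                profile.cells[:, :, 2],
                origin="lower",
                aspect="auto",
                extent=(
                    profile.axis2.min(),
                    profile.axis2.max(),
                    profile.axis1.min(),
                    profile.axis1.max(),
                ),
            )
            fig.colorbar(im, ax=ax, label="remaining VLFs")
            ax.set_xlabel("3' trim (bp)")
            ax.set_ylabel("5' trim (bp)")
        else:
            ax.plot(profile.axis1, profile.cells[:, 0, 0], label="singleton")
            ax.plot(profile.axis1, profile.cells[:, 0, 1], label="shared")
            ax.plot(profile.axis1, profile.cells[:, 0, 2], label="total")
            ax.set_xscale("log")
            ax.set_xlabel("cutoff frequency p")
            ax.set_ylabel("VLF count")
            ax.legend()
    else:
        raise TypeError(f"cannot render {type(profile).__name__}")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
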