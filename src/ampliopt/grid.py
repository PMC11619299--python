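"""Stepwise trim-length optimization over a (forward, reverse) grid.

Paired-end amplicon reads must be truncated before merging: too little
trimming keeps low-quality 3' tails that fail the expected-errors
filter, too much trimming destroys the overlap (or exceeds the available
template) and merging collapses.  This module enumerates a truncation
grid — 90..230 bp in steps of 10 for 250 bp paired-end reads, 90..280 bp
for 300 bp reads — runs the denoising emulator in every cell against the
same input, and selects the cell that maximizes non-chimeric read
survival.

The quality-profile heuristic ``suggest_trim_by_quality`` implements the
common rule of thumb of truncating where the 25th-percentile Phred
quality drops below 20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .denoise import (
    FilterParams,
    MergeParams,
    SurvivalStats,
    _longest_exact_overlap,
    dereplicate,
    merge_pair,
    remove_bimeras,
    survival_stats,
)
from .primers import TrimPair, overlap_length, reverse_complement

__all__ = [
    "GRID_PRESETS",
    "GridSpec",
    "GridResult",
    "enumerate_grid",
    "suggest_trim_by_quality",
    "optimize_trim",
    "table1_report",
    "surface_frame",
    "plot_survival_surface",
]

#: read length -> (start, stop, step): 15 grid positions for 250 bp
#: paired-end reads, 20 positions for 300 bp.
GRID_PRESETS: dict[int, tuple[int, int, int]] = {250: (90, 230, 10), 300: (90, 280, 10)}


@dataclass(frozen=True)
class GridSpec:
    """Arithmetic truncation-length sequence used for both read directions."""

    start: int
    stop: int
    step: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"start {self.start} > stop {self.stop}")
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if (self.stop - self.start) % self.step:
            raise ValueError(
                f"stop - start ({self.stop - self.start}) not divisible by step {self.step}"
            )

    @classmethod
    def preset(cls, read_len: int) -> "GridSpec":
        try:
            return cls(*GRID_PRESETS[read_len])
        except KeyError:
            raise KeyError(
                f"no grid preset for read length {read_len}; known: {sorted(GRID_PRESETS)}"
            ) from None

    @property
    def positions(self) -> list[int]:
        return list(range(self.start, self.stop + 1, self.step))


@dataclass
class GridResult:
    """Survival surface over the grid plus the winning cell."""

    primer: str
    cells: dict[TrimPair, SurvivalStats]
    best: TrimPair
    degenerate: bool = False
    best_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.best not in self.cells:
            raise ValueError("best cell is not part of the surface")

    @property
    def best_stats(self) -> SurvivalStats:
        return self.cells[self.best]


def enumerate_grid(spec: GridSpec) -> list[TrimPair]:
    """All ordered (forward, reverse) trim pairs of a spec, row-major.

    The count is ``((stop - start) / step + 1) ** 2``: 225 pairs for the
    250 bp preset and 400 for the 300 bp preset.
    """
    pos = spec.positions
    return [TrimPair(f, r) for f in pos for r in pos]


def suggest_trim_by_quality(
    profile: np.ndarray | Sequence[float],
    percentile: float = 25.0,
    q_threshold: float = 20.0,
) -> int:
    """Longest truncation whose chosen-percentile quality stays >= threshold.

    ``profile`` is either a 1-D per-position quality percentile profile
    or a 2-D (reads x positions) Phred matrix from which the percentile
    is taken per position.  Returns the largest 1-based position at
    which the percentile quality is still at or above ``q_threshold``;
    0 (with a warning) if quality is below threshold everywhere.
    """
    arr = np.asarray(profile, dtype=float)
    if arr.size == 0:
        raise ValueError("empty quality profile")
    if arr.ndim == 2:
        arr = np.percentile(arr, percentile, axis=0)
    elif arr.ndim != 1:
        raise ValueError(f"profile must be 1-D or 2-D, got shape {arr.shape}")
    good = np.flatnonzero(arr >= q_threshold)
    if good.size == 0:
        warnings.warn(
            f"quality never reaches {q_threshold} at the {percentile}th percentile",
            stacklevel=2,
        )
        return 0
    return int(good[-1]) + 1


class _Prepared:
    """Per-read precomputation shared by every grid cell."""

    def __init__(self, pairs: Sequence) -> None:
        self.n = len(pairs)
        self.fwd_seqs = [p.fwd_seq for p in pairs]
        self.rc_seqs = [reverse_complement(p.rev_seq) for p in pairs]
        self.fwd_quals = [np.asarray(p.fwd_qual) for p in pairs]
        self.rev_quals = [np.asarray(p.rev_qual) for p in pairs]
        self.fwd_lens = np.array([len(s) for s in self.fwd_seqs])
        self.rev_lens = np.array([len(q) for q in self.rev_quals])
        self.fwd_ee = [np.cumsum(10.0 ** (-q / 10.0)) for q in self.fwd_quals]
        self.rev_ee = [np.cumsum(10.0 ** (-q / 10.0)) for q in self.rev_quals]


def _evaluate_cell(
    prep: _Prepared,
    trim: TrimPair,
    max_expected_errors: float,
    merge_params: MergeParams,
    collapse: bool,
    collapse_fold: float,
    parent_fold: float,
) -> tuple[SurvivalStats, pd.DataFrame]:
    tf, tr = trim.fwd_trim, trim.rev_trim
    n_filtered = 0
    merged: list[str] = []
    exact = merge_params.max_mismatch_in_overlap == 0
    for i in range(prep.n):
        if prep.fwd_lens[i] < tf or prep.rev_lens[i] < tr:
            continue
        if prep.fwd_ee[i][tf - 1] > max_expected_errors:
            continue
        if prep.rev_ee[i][tr - 1] > max_expected_errors:
            continue
        n_filtered += 1
        fwd_t = prep.fwd_seqs[i][:tf]
        rc_t = prep.rc_seqs[i][prep.rev_lens[i] - tr :]
        if exact:
            o = _longest_exact_overlap(fwd_t, rc_t, merge_params.min_overlap)
            if o >= 0:
                merged.append(fwd_t + rc_t[o:])
        else:
            m = merge_pair(
                fwd_t,
                prep.fwd_quals[i][:tf],
                reverse_complement(rc_t),
                prep.rev_quals[i][:tr],
                merge_params,
            )
            if m is not None:
                merged.append(m)
    table = dereplicate(merged, collapse=collapse, collapse_fold=collapse_fold)
    table, _, _ = remove_bimeras(table, parent_fold=parent_fold)
    nonchim = int(table.to_numpy().sum()) if not table.empty else 0
    stats = survival_stats(prep.n, n_filtered, len(merged), nonchim)
    return stats, table


def optimize_trim(
    pairs: Sequence,
    spec: GridSpec,
    max_expected_errors: float = 2.0,
    merge_params: MergeParams = MergeParams(),
    collapse: bool = True,
    collapse_fold: float = 8.0,
    parent_fold: float = 2.0,
    primer: str = "",
    max_pairs: int | None = None,
    subsample_seed: int = 0,
) -> GridResult:
    """Evaluate every grid cell on the same input and pick the argmax.

    The winner maximizes the non-chimeric read count; ties are broken by
    the larger total retained length ``fwd + rev``, then the larger
    forward trim.  ``max_pairs`` evaluates the surface on a seeded
    random subsample (the full input is never required to rank cells —
    survival fractions are what is compared).  If every cell retains
    zero reads the result is flagged degenerate but ``best`` is still
    defined by the tie-break.
    """
    if not pairs:
        raise ValueError("optimize_trim needs a non-empty input")
    if max_pairs is not None and max_pairs < len(pairs):
        rng = np.random.default_rng(subsample_seed)
        idx = sorted(rng.choice(len(pairs), size=max_pairs, replace=False))
        pairs = [pairs[i] for i in idx]
    prep = _Prepared(pairs)
    cells: dict[TrimPair, SurvivalStats] = {}
    tables: dict[TrimPair, pd.DataFrame] = {}
    for trim in enumerate_grid(spec):
        stats, table = _evaluate_cell(
            prep, trim, max_expected_errors, merge_params, collapse, collapse_fold, parent_fold
        )
        cells[trim] = stats
        tables[trim] = table
    best = max(
        cells,
        key=lambda t: (cells[t].nonchimeric, t.fwd_trim + t.rev_trim, t.fwd_trim),
    )
    degenerate = cells[best].nonchimeric == 0
    if degenerate:
        warnings.warn("every grid cell retained zero non-chimeric reads", stacklevel=2)
    return GridResult(
        primer=primer, cells=cells, best=best, degenerate=degenerate, best_table=tables[best]
    )


def surface_frame(result: GridResult) -> pd.DataFrame:
    """Tidy survival surface: one row per cell with the three percentages."""
    rows = [
        {
            "fwd": t.fwd_trim,
            "rev": t.rev_trim,
            "filtered_pct": s.filtered_pct,
            "merged_pct": s.merged_pct,
            "nonchimeric_pct": s.nonchimeric_pct,
        }
        for t, s in result.cells.items()
    ]
    return pd.DataFrame(rows)


def table1_report(
    results: Iterable[GridResult], amplicon_lens: dict[str, int]
) -> pd.DataFrame:
    """Per-primer summary of the winning trim cell.

    Columns mirror the conventional survival-summary layout: primer,
    forward/reverse trim, overlap (negative overlaps are printed as the
    literal "Less than 0"), and the three survival percentages to two
    decimals.  All trim and overlap lengths are post-primer-removal.
    """
    rows = []
    for res in results:
        t = res.best
        s = res.best_stats
        ov = overlap_length(t, amplicon_lens[res.primer])
        rows.append(
            {
                "Primer": res.primer,
                "Forward (bp)": t.fwd_trim,
                "Reverse (bp)": t.rev_trim,
                "Overlap (bp)": str(ov) if ov >= 0 else "Less than 0",
                "Filtered (%)": f"{s.filtered_pct:.2f}",
                "Merged (%)": f"{s.merged_pct:.2f}",
                "Non-chimeric (%)": f"{s.nonchimeric_pct:.2f}",
            }
        )
    return pd.DataFrame(rows)


def plot_survival_surface(result: GridResult, path: str) -> None:
    """Heatmap of non-chimeric survival over the trim grid (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = surface_frame(result).pivot(index="rev", columns="fwd", values="nonchimeric_pct")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        df.to_numpy(),
        origin="lower",
        aspect="auto",
        extent=(
            df.columns.min(), df.columns.max(), df.index.min(), df.index.max()
        ),
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="non-chimeric survival (%)")
    b = result.best
    ax.plot(b.fwd_trim, b.rev_trim, "r*", markersize=12)
    ax.set_xlabel("forward trim (bp)")
    ax.set_ylabel("reverse trim (bp)")
    ax.set_title(f"{result.primer or 'survival surface'}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
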