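"""Simplified paired-end denoising: filter, merge, dereplicate, de-bimera.

This stage reproduces the *accounting* of an amplicon denoiser — the
fraction of read pairs surviving quality filtering, merging, and chimera
removal, plus an ASV count table — without re-implementing a learned
error model.  The stand-in for error-model denoising is exact
dereplication followed by an abundance-ratio collapse of Hamming-
distance-1 neighbours; this is the central simplification of the package
and is documented in docs/methods.md.

Stages
------
1. ``truncate_and_filter`` — truncate both mates to fixed lengths and
   drop pairs that are too short or exceed the expected-errors budget
   (EE = sum of 10**(-Q/10) over the truncated read).
2. ``merge_pairs`` — align the forward read's 3' end against the
   reverse-complemented reverse read and join at the longest exact (or
   near-exact) overlap of at least ``min_overlap`` bases.
3. ``dereplicate`` — exact-identity grouping into ASVs with the optional
   distance-1 collapse.
4. ``remove_bimeras`` — flag ASVs that can be split into a prefix of one
   sufficiently more abundant ASV and a suffix of another.

The survival chain is monotone by construction: every stage consumes the
previous stage's survivors.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .primers import reverse_complement

__all__ = [
    "FilterParams",
    "MergeParams",
    "SurvivalStats",
    "TruncatedPair",
    "expected_errors",
    "truncate_and_filter",
    "merge_pair",
    "merge_pairs",
    "dereplicate",
    "remove_bimeras",
    "survival_stats",
]


@dataclass(frozen=True)
class FilterParams:
    """Truncation lengths and the per-read expected-errors budget."""

    trunc_len_f: int
    trunc_len_r: int
    max_expected_errors: float = 2.0

    def __post_init__(self) -> None:
        if self.trunc_len_f < 1 or self.trunc_len_r < 1:
            raise ValueError("truncation lengths must be >= 1")
        if self.max_expected_errors <= 0:
            raise ValueError("max_expected_errors must be > 0")


@dataclass(frozen=True)
class MergeParams:
    """Minimum overlap and mismatch tolerance for pair merging."""

    min_overlap: int = 16
    max_mismatch_in_overlap: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_mismatch_in_overlap < 0:
            raise ValueError("max_mismatch_in_overlap must be >= 0")


@dataclass(frozen=True)
class SurvivalStats:
    """Read-pair survival through filter / merge / chimera-removal.

    Counts are exact; percentages (of ``input_pairs``) are exposed as
    properties and rounded only at presentation time.
    """

    input_pairs: int
    filtered: int
    merged: int
    nonchimeric: int

    def __post_init__(self) -> None:
        chain = (self.input_pairs, self.filtered, self.merged, self.nonchimeric)
        if any(c < 0 for c in chain):
            raise ValueError(f"negative stage count in {chain}")
        if not (chain[0] >= chain[1] >= chain[2] >= chain[3]):
            raise ValueError(f"survival chain must be non-increasing, got {chain}")
        if self.input_pairs == 0:
            warnings.warn("survival stats over zero input pairs", stacklevel=3)

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.input_pairs if self.input_pairs else 0.0

    @property
    def filtered_pct(self) -> float:
        return self._pct(self.filtered)

    @property
    def merged_pct(self) -> float:
        return self._pct(self.merged)

    @property
    def nonchimeric_pct(self) -> float:
        return self._pct(self.nonchimeric)


@dataclass(frozen=True)
class TruncatedPair:
    """A filtered, truncated read pair ready for merging."""

    read_id: str
    fwd_seq: str
    fwd_qual: np.ndarray
    rev_seq: str
    rev_qual: np.ndarray


def expected_errors(quality: np.ndarray | Sequence[int]) -> float:
    """Expected number of errors of a read: sum of 10**(-Q/10)."""
    q = np.asarray(quality, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def truncate_and_filter(pairs: Iterable, params: FilterParams) -> tuple[list[TruncatedPair], int]:
    """Truncate both mates and drop short or low-quality pairs.

    A pair survives iff both mates are at least as long as their
    truncation length and both truncated mates satisfy the
    expected-errors budget.  Returns ``(survivors, n_survivors)``.
    """
    tf, tr = params.trunc_len_f, params.trunc_len_r
    kept: list[TruncatedPair] = []
    for p in pairs:
        if len(p.fwd_seq) < tf or len(p.rev_seq) < tr:
            continue
        fq = np.asarray(p.fwd_qual)[:tf]
        rq = np.asarray(p.rev_qual)[:tr]
        if expected_errors(fq) > params.max_expected_errors:
            continue
        if expected_errors(rq) > params.max_expected_errors:
            continue
        kept.append(
            TruncatedPair(
                read_id=getattr(p, "read_id", ""),
                fwd_seq=p.fwd_seq[:tf],
                fwd_qual=fq,
                rev_seq=p.rev_seq[:tr],
                rev_qual=rq,
            )
        )
    return kept, len(kept)


def _longest_exact_overlap(fwd: str, rc: str, min_overlap: int) -> int:
    """Longest o >= min_overlap with fwd[-o:] == rc[:o]; -1 if none.

    Seeded search: any qualifying overlap must place the last
    ``min_overlap`` bases of the forward read somewhere in the
    reverse-complemented mate, so only positions where that seed occurs
    are checked.
    """
    if len(fwd) < min_overlap or len(rc) < min_overlap:
        return -1
    seed = fwd[-min_overlap:]
    cap = min(len(fwd), len(rc))
    best = -1
    pos = rc.find(seed)
    while pos != -1:
        o = pos + min_overlap
        if o <= cap and o > best and fwd[len(fwd) - o :] == rc[:o]:
            best = o
        pos = rc.find(seed, pos + 1)
    return best


def merge_pair(
    fwd_seq: str,
    fwd_qual: np.ndarray,
    rev_seq: str,
    rev_qual: np.ndarray,
    params: MergeParams = MergeParams(),
) -> str | None:
    """Merge one truncated pair; None on merge failure.

    The reverse read is reverse-complemented and aligned under the
    forward read's 3' end; the longest overlap of at least
    ``min_overlap`` bases with at most ``max_mismatch_in_overlap``
    mismatches is accepted.  Where the overlap disagrees (only possible
    when mismatches are allowed) the base with the higher Phred score
    wins.  Merged length is ``len(fwd) + len(rev) - overlap``.
    """
    rc = reverse_complement(rev_seq)
    if params.max_mismatch_in_overlap == 0:
        o = _longest_exact_overlap(fwd_seq, rc, params.min_overlap)
        if o < 0:
            return None
        return fwd_seq + rc[o:]

    rcq = np.asarray(rev_qual)[::-1]
    fq = np.asarray(fwd_qual)
    lf, lr = len(fwd_seq), len(rc)
    for o in range(min(lf, lr), params.min_overlap - 1, -1):
        a = fwd_seq[lf - o :]
        b = rc[:o]
        mism = [k for k in range(o) if a[k] != b[k]]
        if len(mism) > params.max_mismatch_in_overlap:
            continue
        if not mism:
            return fwd_seq + rc[o:]
        overlap = list(a)
        for k in mism:
            if rcq[k] > fq[lf - o + k]:
                overlap[k] = b[k]
        return fwd_seq[: lf - o] + "".join(overlap) + rc[o:]
    return None


def merge_pairs(
    pairs: Sequence[TruncatedPair], params: MergeParams = MergeParams()
) -> tuple[list[tuple[str, str]], int]:
    """Merge all pairs; returns ``([(read_id, merged_seq), ...], n_failures)``."""
    merged: list[tuple[str, str]] = []
    failures = 0
    for p in pairs:
        m = merge_pair(p.fwd_seq, p.fwd_qual, p.rev_seq, p.rev_qual, params)
        if m is None:
            failures += 1
        else:
            merged.append((p.read_id, m))
    return merged, failures


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def dereplicate(
    sequences: Sequence[str],
    samples: Sequence[str] | None = None,
    collapse: bool = True,
    collapse_fold: float = 8.0,
) -> pd.DataFrame:
    """Exact-identity ASV table (rows: sequence, columns: samples).

    With ``collapse`` on, any sequence is absorbed into a
    Hamming-distance-1 neighbour whose total abundance is at least
    ``collapse_fold`` times its own — a minimal stand-in for error-model
    denoising that soaks up singleton sequencing errors.  The collapse
    is a single pass against pre-collapse abundances, most-abundant
    neighbour first.
    """
    if samples is None:
        samples = ["sample1"] * len(sequences)
    if len(samples) != len(sequences):
        raise ValueError("sequences and samples must have equal length")
    if not sequences:
        return pd.DataFrame(index=pd.Index([], name="sequence"))
    counts: Counter[tuple[str, str]] = Counter(zip(sequences, samples))
    table = (
        pd.Series(counts)
        .unstack(fill_value=0)
        .rename_axis(index="sequence", columns="sample")
        .sort_index()
    )
    if not collapse or table.empty:
        return table

    totals = table.sum(axis=1)
    seqs = list(table.index)
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)

    absorb: dict[str, str] = {}
    for length, group in by_len.items():
        if len(group) < 2:
            continue
        g_tot = totals[group].to_numpy()
        mat = _encode(group)
        # only sequences this abundant can absorb anything
        tgt_idx = np.flatnonzero(g_tot >= collapse_fold)
        if tgt_idx.size == 0:
            continue
        tgt = mat[tgt_idx]
        dist = (mat[:, None, :] != tgt[None, :, :]).sum(axis=2)
        for i, s in enumerate(group):
            ok = np.flatnonzero(
                (dist[i] == 1) & (g_tot[tgt_idx] >= collapse_fold * g_tot[i])
            )
            if ok.size:
                # highest-abundance neighbour, ties by sequence order
                cands = sorted(
                    (int(j) for j in ok),
                    key=lambda j: (-g_tot[tgt_idx[j]], group[tgt_idx[j]]),
                )
                absorb[s] = group[tgt_idx[cands[0]]]
    if absorb:
        def resolve(s: str) -> str:
            seen = {s}
            while s in absorb and absorb[s] not in seen:
                s = absorb[s]
                seen.add(s)
            return s

        table = table.groupby(
            [resolve(s) for s in table.index]
        ).sum().rename_axis(index="sequence")
    return table.sort_index()


def _lcp_lcs(children: np.ndarray, parents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per (child, parent) longest common prefix and suffix lengths."""
    length = children.shape[1]
    neq = children[:, None, :] != parents[None, :, :]
    any_neq = neq.any(axis=2)
    first = neq.argmax(axis=2)
    lcp = np.where(any_neq, first, length)
    neq_r = neq[:, :, ::-1]
    first_r = neq_r.argmax(axis=2)
    lcs = np.where(any_neq, first_r, length)
    return lcp, lcs


def remove_bimeras(
    table: pd.DataFrame, parent_fold: float = 2.0
) -> tuple[pd.DataFrame, int, list[str]]:
    """Drop ASVs explainable as a two-parent chimera.

    An ASV is flagged iff two *distinct* ASVs A and B exist, each with
    total abundance at least ``parent_fold`` times the ASV's own, such
    that the ASV equals a prefix of A followed by a suffix of B at some
    split point (equal sequence lengths; the simulator produces
    substitution-only variation, so chimeric amplicons keep their
    parents' length).  The single most abundant ASV can never be
    flagged.

    Returns ``(cleaned table, reads removed, flagged sequences)``.
    """
    if table.empty:
        return table, 0, []
    totals = table.sum(axis=1)
    flagged: list[str] = []

    by_len: dict[int, list[str]] = {}
    for s in table.index:
        by_len.setdefault(len(s), []).append(s)

    for length, group in by_len.items():
        if len(group) < 3:
            continue
        g_tot = totals[group].to_numpy().astype(float)
        pool_idx = np.flatnonzero(g_tot >= parent_fold * g_tot.min())
        if pool_idx.size < 2:
            continue
        mat = _encode(group)
        lcp, lcs = _lcp_lcs(mat, mat[pool_idx])
        for i, s in enumerate(group):
            ok = np.flatnonzero(
                (g_tot[pool_idx] >= parent_fold * g_tot[i]) & (pool_idx != i)
            )
            if ok.size < 2:
                continue
            l1, l2 = lcp[i][ok], lcs[i][ok]
            a_star = int(np.argmax(l1))
            b_star = int(np.argmax(l2))
            if a_star != b_star:
                if l1[a_star] + l2[b_star] >= length:
                    flagged.append(s)
                continue
            # best prefix and suffix parent coincide; try second bests
            l1_second = np.partition(l1, -2)[-2] if ok.size > 1 else -1
            l2_second = np.partition(l2, -2)[-2] if ok.size > 1 else -1
            if (
                l1[a_star] + l2_second >= length
                or l1_second + l2[b_star] >= length
            ):
                flagged.append(s)

    if not flagged:
        return table, 0, []
    removed = int(totals[flagged].sum())
    return table.drop(index=flagged), removed, flagged


def survival_stats(
    input_pairs: int, filtered: int, merged: int, nonchimeric: int
) -> SurvivalStats:
    """Bundle the stage counts; percentages are derived lazily."""
    return SurvivalStats(
        input_pairs=input_pairs, filtered=filtered, merged=merged, nonchimeric=nonchimeric
    )
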