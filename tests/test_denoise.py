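"""Denoising emulator: filtering, merging, dereplication, bimera removal.

Includes the brute-force oracle check: on small inputs every stage must
agree with a direct nested-loop re-implementation.
"""

import numpy as np
import pandas as pd
import pytest

from ampliopt.denoise import (
    FilterParams,
    MergeParams,
    SurvivalStats,
    dereplicate,
    expected_errors,
    merge_pair,
    merge_pairs,
    remove_bimeras,
    survival_stats,
    truncate_and_filter,
)
from ampliopt.primers import reverse_complement
from ampliopt.simulate import SimConfig, simulate_pairs


def _pair(fwd, rev, fq=None, rq=None, rid="r1"):
    from ampliopt.denoise import TruncatedPair

    fq = np.full(len(fwd), 35) if fq is None else np.asarray(fq)
    rq = np.full(len(rev), 35) if rq is None else np.asarray(rq)
    return TruncatedPair(read_id=rid, fwd_seq=fwd, fwd_qual=fq, rev_seq=rev, rev_qual=rq)


class TestFilter:
    def test_expected_errors_closed_form(self):
        assert expected_errors(np.full(300, 30)) == pytest.approx(0.3)
        assert expected_errors(np.full(300, 20)) == pytest.approx(3.0)

    def test_quality_budget(self):
        good = _pair("A" * 300, "C" * 300, np.full(300, 30), np.full(300, 30))
        bad = _pair("A" * 300, "C" * 300, np.full(300, 20), np.full(300, 30))
        params = FilterParams(300, 300, max_expected_errors=2.0)
        kept, n = truncate_and_filter([good, bad], params)
        assert n == 1 and kept[0].read_id == "r1"

    def test_short_read_discarded(self):
        p = _pair("A" * 200, "C" * 300)
        kept, n = truncate_and_filter([p], FilterParams(250, 250))
        assert n == 0 and kept == []

    def test_empty_input(self):
        kept, n = truncate_and_filter([], FilterParams(100, 100))
        assert kept == [] and n == 0

    def test_truncation_applied_before_ee(self):
        # tail is terrible but the truncated prefix passes
        q = np.concatenate([np.full(100, 38), np.full(200, 2)])
        p = _pair("A" * 300, "C" * 300, q, q)
        kept, n = truncate_and_filter([p], FilterParams(100, 100, 2.0))
        assert n == 1
        assert len(kept[0].fwd_seq) == 100


class TestMerge:
    def test_error_free_pair_reconstructs_template(self):
        rng = np.random.default_rng(4)
        template = "".join(rng.choice(list("ACGT"), size=427))
        fwd = template[:230]
        rev = reverse_complement(template)[:220]
        merged = merge_pair(fwd, np.full(230, 35), rev, np.full(220, 35))
        assert merged == template
        assert len(merged) == 427  # overlap 23

    def test_overlap_below_minimum_fails(self):
        rng = np.random.default_rng(5)
        template = "".join(rng.choice(list("ACGT"), size=300))
        fwd = template[:155]
        rev = reverse_complement(template)[:155]  # overlap 10
        assert merge_pair(fwd, np.full(155, 35), rev, np.full(155, 35)) is None

    def test_one_mismatch_fails_at_zero_budget(self):
        rng = np.random.default_rng(6)
        template = "".join(rng.choice(list("ACGT"), size=300))
        fwd = list(template[:170])
        fwd[-20] = "A" if fwd[-20] != "A" else "C"  # inside the 40 bp overlap
        rev = reverse_complement(template)[:170]
        assert merge_pair("".join(fwd), np.full(170, 35), rev, np.full(170, 35)) is None

    def test_mismatch_resolved_by_higher_quality(self):
        rng = np.random.default_rng(7)
        template = "".join(rng.choice(list("ACGT"), size=300))
        fwd = list(template[:170])
        pos = 150  # inside the overlap
        fwd[pos] = "A" if fwd[pos] != "A" else "C"
        fq = np.full(170, 20)
        rev = reverse_complement(template)[:170]
        rq = np.full(170, 38)  # reverse read more trustworthy
        merged = merge_pair(
            "".join(fwd), fq, rev, rq, MergeParams(max_mismatch_in_overlap=1)
        )
        assert merged == template

    def test_longest_qualifying_overlap_wins(self):
        # an A-run junction makes every overlap 16..40 qualify; the
        # merger must take the longest (40), not the first >= 16
        rng = np.random.default_rng(12)
        left = "".join(rng.choice(list("CGT"), size=80))
        right = "".join(rng.choice(list("CGT"), size=80))
        fwd = left + "A" * 40
        rc = "A" * 40 + right
        merged = merge_pair(fwd, np.full(120, 35), reverse_complement(rc), np.full(120, 35))
        assert merged == left + "A" * 40 + right


class TestDereplicate:
    def test_identical_sequences_one_asv(self):
        t = dereplicate(["ACGT"] * 100)
        assert list(t.index) == ["ACGT"]
        assert int(t.iloc[0, 0]) == 100

    def test_distance_one_collapse(self):
        seqs = ["ACGTACGT"] * 99 + ["ACGTACGA"]
        t = dereplicate(seqs, collapse=True, collapse_fold=8.0)
        assert list(t.index) == ["ACGTACGT"]
        assert int(t.iloc[0, 0]) == 100

    def test_distance_two_not_collapsed(self):
        seqs = ["ACGTACGT"] * 99 + ["ACGTACAA"]
        t = dereplicate(seqs)
        assert len(t) == 2

    def test_collapse_respects_abundance_fold(self):
        seqs = ["ACGTACGT"] * 7 + ["ACGTACGA"]  # 7 < 8x1
        t = dereplicate(seqs, collapse_fold=8.0)
        assert len(t) == 2

    def test_per_sample_columns(self):
        t = dereplicate(["AAAA", "AAAA", "CCCC"], samples=["s1", "s2", "s1"], collapse=False)
        assert t.loc["AAAA", "s1"] == 1 and t.loc["AAAA", "s2"] == 1
        assert t.loc["CCCC", "s1"] == 1


class TestBimeras:
    def test_clean_table_unchanged(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        t = dereplicate([s for s in seqs for _ in range(50)])
        out, removed, flagged = remove_bimeras(t)
        assert removed == 0 and flagged == [] and out.equals(t)

    def test_injected_chimera_removed(self):
        rng = np.random.default_rng(9)
        a = "".join(rng.choice(list("ACGT"), size=80))
        b = "".join(rng.choice(list("ACGT"), size=80))
        chimera = a[:40] + b[40:]
        t = dereplicate([a] * 1000 + [b] * 1000 + [chimera] * 10, collapse=False)
        out, removed, flagged = remove_bimeras(t, parent_fold=2.0)
        assert flagged == [chimera]
        assert removed == 10
        assert chimera not in out.index

    def test_most_abundant_never_flagged(self):
        rng = np.random.default_rng(10)
        a = "".join(rng.choice(list("ACGT"), size=80))
        b = "".join(rng.choice(list("ACGT"), size=80))
        chimera = a[:40] + b[40:]
        # the "chimera" dominates: no parent can be 2x more abundant
        t = dereplicate([a] * 10 + [b] * 10 + [chimera] * 1000, collapse=False)
        _, removed, flagged = remove_bimeras(t)
        assert chimera not in flagged and removed == 0

    def test_parents_must_be_sufficiently_abundant(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(list("ACGT"), size=80))
        b = "".join(rng.choice(list("ACGT"), size=80))
        chimera = a[:40] + b[40:]
        t = dereplicate([a] * 15 + [b] * 15 + [chimera] * 10, collapse=False)
        _, _, flagged = remove_bimeras(t, parent_fold=2.0)
        assert flagged == []  # 15 < 2 x 10


class TestSurvivalStats:
    def test_percentages(self):
        s = survival_stats(10000, 9000, 8500, 8000)
        assert (s.filtered_pct, s.merged_pct, s.nonchimeric_pct) == (90.0, 85.0, 80.0)

    def test_all_survive(self):
        s = survival_stats(500, 500, 500, 500)
        assert s.filtered_pct == s.merged_pct == s.nonchimeric_pct == 100.0

    def test_zero_input_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            s = survival_stats(0, 0, 0, 0)
        assert s.filtered_pct == 0.0

    def test_non_monotone_chain_rejected(self):
        with pytest.raises(ValueError):
            survival_stats(100, 90, 95, 80)


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence on a small simulated batch.


def _brute_overlap(fwd: str, rc: str, min_ov: int) -> int:
    best = -1
    for o in range(min_ov, min(len(fwd), len(rc)) + 1):
        if fwd[len(fwd) - o :] == rc[:o]:
            best = o
    return best


def _brute_stage_counts(reads, tf, tr, max_ee, min_ov):
    filtered = []
    for r in reads:
        if len(r.fwd_seq) < tf or len(r.rev_seq) < tr:
            continue
        fe = sum(10.0 ** (-q / 10.0) for q in np.asarray(r.fwd_qual)[:tf])
        re_ = sum(10.0 ** (-q / 10.0) for q in np.asarray(r.rev_qual)[:tr])
        if fe > max_ee or re_ > max_ee:
            continue
        filtered.append(r)
    merged = []
    for r in filtered:
        fwd = r.fwd_seq[:tf]
        rc = reverse_complement(r.rev_seq[:tr])
        o = _brute_overlap(fwd, rc, min_ov)
        if o >= 0:
            merged.append(fwd + rc[o:])
    return filtered, merged


def test_oracle_equivalence_on_small_batch(noisy_reads_v34):
    reads = noisy_reads_v34[:200]
    tf, tr, max_ee, min_ov = 230, 200, 2.0, 16
    oracle_filtered, oracle_merged = _brute_stage_counts(reads, tf, tr, max_ee, min_ov)

    kept, n_filtered = truncate_and_filter(reads, FilterParams(tf, tr, max_ee))
    assert n_filtered == len(oracle_filtered)
    merged, n_fail = merge_pairs(kept, MergeParams(min_overlap=min_ov))
    assert sorted(m for _, m in merged) == sorted(oracle_merged)
    assert n_fail == len(oracle_filtered) - len(oracle_merged)
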