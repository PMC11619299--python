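"""Trim-grid enumeration, quality heuristic, and optimization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampliopt.denoise import FilterParams, MergeParams, dereplicate, merge_pairs, remove_bimeras, truncate_and_filter
from ampliopt.grid import (
    GridSpec,
    enumerate_grid,
    optimize_trim,
    suggest_trim_by_quality,
    surface_frame,
    table1_report,
)
from ampliopt.primers import TrimPair
from ampliopt.simulate import ERROR_FREE_QUALITY, QualityModel, SimConfig, simulate_pairs


class TestEnumerateGrid:
    def test_preset_cardinalities(self):
        assert len(enumerate_grid(GridSpec(90, 230, 10))) == 225
        assert len(enumerate_grid(GridSpec(90, 280, 10))) == 400

    def test_single_cell(self):
        assert enumerate_grid(GridSpec(100, 100, 10)) == [TrimPair(100, 100)]

    def test_row_major_deterministic_order(self):
        cells = enumerate_grid(GridSpec(100, 120, 10))
        assert cells[:3] == [TrimPair(100, 100), TrimPair(100, 110), TrimPair(100, 120)]

    @given(
        start=st.integers(10, 200),
        n_steps=st.integers(0, 12),
        step=st.integers(1, 25),
    )
    def test_cardinality_formula(self, start, n_steps, step):
        spec = GridSpec(start, start + n_steps * step, step)
        assert len(enumerate_grid(spec)) == (n_steps + 1) ** 2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(200, 100, 10)
        with pytest.raises(ValueError):
            GridSpec(90, 230, 0)
        with pytest.raises(ValueError):
            GridSpec(90, 235, 10)

    def test_preset_lookup(self):
        assert GridSpec.preset(250) == GridSpec(90, 230, 10)
        with pytest.raises(KeyError):
            GridSpec.preset(150)


class TestSuggestTrim:
    def test_constant_profile_keeps_full_length(self):
        assert suggest_trim_by_quality(np.full(300, 30.0)) == 300

    def test_crossing_profile(self):
        # quality >= 20 through position 240, below from 241 on
        profile = np.where(np.arange(1, 301) <= 240, 28.0, 12.0)
        assert suggest_trim_by_quality(profile) == 240

    def test_all_below_threshold_warns_zero(self):
        with pytest.warns(UserWarning):
            assert suggest_trim_by_quality(np.full(100, 10.0)) == 0

    def test_percentile_taken_from_matrix(self):
        # half the reads are terrible: the 25th percentile sits in the bad
        # half while the 75th still sees the good reads
        mat = np.vstack([np.full((2, 50), 35.0), np.full((2, 50), 5.0)])
        with pytest.warns(UserWarning):
            assert suggest_trim_by_quality(mat, percentile=25) == 0
        assert suggest_trim_by_quality(mat, percentile=75) == 50

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            suggest_trim_by_quality(np.array([]))


def _oracle_best(reads, spec, max_ee=2.0, min_ov=16):
    """Independent re-run: direct stage calls per cell, same tie-break."""
    best, best_key = None, None
    for trim in enumerate_grid(spec):
        kept, _ = truncate_and_filter(reads, FilterParams(trim.fwd_trim, trim.rev_trim, max_ee))
        merged, _ = merge_pairs(kept, MergeParams(min_overlap=min_ov))
        table = dereplicate([m for _, m in merged])
        table, _, _ = remove_bimeras(table)
        nonchim = int(table.to_numpy().sum()) if not table.empty else 0
        key = (nonchim, trim.fwd_trim + trim.rev_trim, trim.fwd_trim)
        if best_key is None or key > best_key:
            best, best_key = trim, key
    return best


class TestOptimizeTrim:
    def test_error_free_plateau_tie_break(self, mock2_comp):
        # 200 bp amplicons, error-free: every feasible cell is perfect and
        # the tie-break must pick the largest total retained length
        rng = np.random.default_rng(13)
        refs = {t: "".join(rng.choice(list("ACGT"), size=200)) for t in mock2_comp.abundances}
        cfg = SimConfig(
            seed=2, n_pairs=300, read_len=250, pair=None, composition=mock2_comp,
            chimera_rate=0.0, fwd_quality=ERROR_FREE_QUALITY, rev_quality=ERROR_FREE_QUALITY,
        )
        reads = simulate_pairs(cfg, refs)
        res = optimize_trim(reads, GridSpec(90, 230, 10))
        assert res.best == TrimPair(200, 200)
        assert res.best_stats.nonchimeric_pct == 100.0

    def test_best_matches_independent_oracle(self, noisy_reads_v34):
        reads = noisy_reads_v34[:150]
        spec = GridSpec(150, 250, 50)
        res = optimize_trim(reads, spec)
        assert res.best == _oracle_best(reads, spec)

    def test_permutation_invariance(self, noisy_reads_v34):
        reads = list(noisy_reads_v34[:200])
        spec = GridSpec(150, 250, 50)
        res1 = optimize_trim(reads, spec)
        rng = np.random.default_rng(14)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        res2 = optimize_trim(shuffled, spec)
        assert res1.best == res2.best
        assert {t: s.nonchimeric for t, s in res1.cells.items()} == {
            t: s.nonchimeric for t, s in res2.cells.items()
        }

    def test_reverse_quality_collapse_bounds_best_reverse_trim(
        self, mock1_comp, v34_amplicons, primer_pairs
    ):
        # reverse reads decay hard: expected errors exceed the budget
        # beyond ~165 bp, so the winning reverse trim must stay short
        # even though longer trims would give more overlap
        bad_rev = QualityModel(q_start=28.0, q_end=2.0, jitter_sd=0.0)
        cfg = SimConfig(
            seed=15, n_pairs=800, read_len=300, pair=primer_pairs["V3-V4"],
            composition=mock1_comp, chimera_rate=0.0,
            fwd_quality=QualityModel(38.0, 30.0, jitter_sd=0.0), rev_quality=bad_rev,
        )
        reads = simulate_pairs(cfg, v34_amplicons)
        res = optimize_trim(reads, GridSpec(90, 280, 10))
        assert res.best.rev_trim <= 170
        assert res.best_stats.nonchimeric > 0

    def test_under_and_over_trimming_reduce_survival(self, noisy_reads_v34):
        spec = GridSpec(90, 280, 10)
        res = optimize_trim(noisy_reads_v34, spec, max_pairs=800)
        best = res.cells[res.best].nonchimeric
        # over-trimming: no overlap possible at the grid minimum
        assert res.cells[TrimPair(90, 90)].nonchimeric < best
        # under-trimming: keeping the full noisy reverse tail hurts
        assert res.cells[TrimPair(res.best.fwd_trim, 280)].nonchimeric < best

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            optimize_trim([], GridSpec(90, 230, 10))


class TestReports:
    def test_table1_formatting(self, noisy_reads_v34):
        res = optimize_trim(noisy_reads_v34[:300], GridSpec(200, 260, 30), primer="V3-V4")
        df = table1_report([res], {"V3-V4": 411})
        row = df.iloc[0]
        assert row["Primer"] == "V3-V4"
        expected = res.best.fwd_trim + res.best.rev_trim - 411
        assert row["Overlap (bp)"] == (str(expected) if expected >= 0 else "Less than 0")
        # two-decimal percentage strings
        assert row["Non-chimeric (%)"] == f"{res.best_stats.nonchimeric_pct:.2f}"

    def test_negative_overlap_prints_sentinel(self, noisy_reads_v34):
        res = optimize_trim(noisy_reads_v34[:100], GridSpec(90, 120, 30), primer="V3-V4")
        df = table1_report([res], {"V3-V4": 411})
        assert df.iloc[0]["Overlap (bp)"] == "Less than 0"

    def test_percentage_rendering(self):
        # 0.9036 survival renders as "90.36"
        assert f"{90.36:.2f}" == "90.36"

    def test_surface_frame_covers_grid(self, noisy_reads_v34):
        res = optimize_trim(noisy_reads_v34[:100], GridSpec(150, 250, 50))
        df = surface_frame(res)
        assert len(df) == 9
        assert set(df.columns) == {"fwd", "rev", "filtered_pct", "merged_pct", "nonchimeric_pct"}
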