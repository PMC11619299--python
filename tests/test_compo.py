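"""CLR transform, grading, Shannon, Spearman, and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampliopt.compo import (
    GRADE_ACCURATE,
    GRADE_FAIR,
    GRADE_POOR,
    GRADE_UNREGISTERED,
    GradingThresholds,
    clr_transform,
    filter_low_abundance,
    grade_accuracy,
    grade_table,
    multiplicative_zero_replacement,
    pca_clr,
    shannon,
    spearman_vs_theory,
)

positive_comps = st.lists(
    st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=12
)


class TestFilterLowAbundance:
    def test_mean_below_one_removed(self):
        t = pd.DataFrame({"s1": [1], "s2": [1], "s3": [0]}, index=["a"])
        assert filter_low_abundance(t).empty

    def test_mean_exactly_one_retained(self):
        t = pd.DataFrame({"s1": [1], "s2": [1], "s3": [1]}, index=["a"])
        assert len(filter_low_abundance(t)) == 1

    def test_empty_table(self):
        t = pd.DataFrame()
        assert filter_low_abundance(t).empty


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon([100]) == 0.0

    def test_uniform_closed_forms(self):
        assert shannon([1] * 15) == pytest.approx(np.log2(15))  # ~3.907
        assert shannon([7] * 6) == pytest.approx(np.log2(6))  # ~2.585

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])

    def test_scale_invariant(self):
        assert shannon([1, 2, 3]) == pytest.approx(shannon([10, 20, 30]))


class TestCLR:
    def test_hand_example(self):
        out = clr_transform([1.0, 2.0, 4.0])
        assert out == pytest.approx([-np.log(2), 0.0, np.log(2)], abs=1e-9)

    def test_equal_counts_all_zero(self):
        assert clr_transform([5, 5, 5, 5]) == pytest.approx([0, 0, 0, 0], abs=1e-12)

    def test_scale_invariance_exact(self):
        assert clr_transform([10, 20, 40]) == pytest.approx(
            clr_transform([1, 2, 4]), abs=1e-12
        )

    @given(comp=positive_comps)
    def test_zero_sum_property(self, comp):
        assert abs(clr_transform(comp).sum()) <= 1e-10

    @given(comp=positive_comps, scale=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance_property(self, comp, scale):
        a = clr_transform(comp)
        b = clr_transform([x * scale for x in comp])
        assert a == pytest.approx(b, abs=1e-10)

    def test_matches_reference_clr_on_positive_data(self):
        from skbio.stats.composition import clr as skbio_clr

        x = np.array([3.0, 9.0, 1.0, 27.0])
        assert clr_transform(x) == pytest.approx(skbio_clr(x / x.sum()), abs=1e-10)

    def test_zero_replacement_rule(self):
        p = multiplicative_zero_replacement([0.0, 1.0, 3.0])
        # smallest nonzero proportion is 0.25 -> delta 0.125
        assert p[0] == pytest.approx(0.125)
        assert p.sum() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            clr_transform([0.0, 0.0])

    def test_preserves_series_index(self):
        s = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        out = clr_transform(s)
        assert isinstance(out, pd.Series) and list(out.index) == list("abc")


class TestGrading:
    @pytest.mark.parametrize(
        # theo = 1.25 with dyadic offsets keeps the computed percent error
        # exactly representable, so the band edges are tested precisely
        "obs,theo,expected",
        [
            (1.25, 1.25, GRADE_ACCURATE),       # err 0
            (1.3125, 1.25, GRADE_ACCURATE),     # err exactly +5
            (1.1875, 1.25, GRADE_ACCURATE),     # err exactly -5
            (1.3130, 1.25, GRADE_FAIR),         # err just above 5
            (1.375, 1.25, GRADE_FAIR),          # err 10
            (1.5625, 1.25, GRADE_FAIR),         # err exactly +25
            (0.9375, 1.25, GRADE_FAIR),         # err exactly -25
            (1.5630, 1.25, GRADE_POOR),         # err just above 25
            (1.625, 1.25, GRADE_POOR),          # err 30
        ],
    )
    def test_band_boundaries(self, obs, theo, expected):
        assert grade_accuracy(obs, theo) == expected

    def test_negative_theoretical_value(self):
        assert grade_accuracy(-1.04, -1.0) == GRADE_ACCURATE
        assert grade_accuracy(-1.30, -1.0) == GRADE_POOR

    def test_unregistered_dominates(self):
        assert grade_accuracy(1.0, 1.0, registered=False) == GRADE_UNREGISTERED

    def test_zero_theoretical_falls_back_to_absolute(self):
        with pytest.warns(UserWarning):
            assert grade_accuracy(0.03, 0.0) == GRADE_ACCURATE
        with pytest.warns(UserWarning):
            assert grade_accuracy(0.9, 0.0) == GRADE_POOR

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            GradingThresholds(inner=25, outer=5)

    def test_grade_table_alignment_and_registration(self):
        theo = pd.Series({"a": 1.0, "b": -1.0, "c": 0.5})
        obs = pd.Series({"a": 1.02, "b": -1.2, "c": 0.9})
        g = grade_table(obs, theo, registered={"a", "b"})
        assert g["a"] == GRADE_ACCURATE
        assert g["b"] == GRADE_FAIR
        assert g["c"] == GRADE_UNREGISTERED


def _brute_spearman(x, y):
    """Rank-formula oracle (no ties): r = 1 - 6*sum(d^2)/(n(n^2-1))."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    n = len(x)
    return 1 - 6 * (d**2).sum() / (n * (n**2 - 1))


class TestSpearman:
    def test_identity_is_exactly_one(self):
        v = clr_transform([5.0, 1.0, 3.0, 9.0, 2.0])
        r, p = spearman_vs_theory(v, v)
        assert r == 1.0

    def test_reversed_ranks(self):
        r, _ = spearman_vs_theory([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        x = np.array([0.3, -1.2, 2.5, 0.9, -0.4])
        y = np.array([1.1, -0.3, 1.9, -2.0, 0.7])
        r, _ = spearman_vs_theory(x, y)
        assert r == pytest.approx(_brute_spearman(x, y))

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning):
            r, p = spearman_vs_theory([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_vs_theory([1, 2], [2, 1])


class TestPCA:
    def test_identical_samples_have_equal_coordinates(self):
        m = pd.DataFrame([[1.0, -1.0, 0.0]] * 3, index=["s1", "s2", "s3"])
        coords, var = pca_clr(m)
        assert np.allclose(coords.to_numpy(), 0.0)
        assert var[0] == pytest.approx(0.0)

    def test_variance_conservation(self):
        rng = np.random.default_rng(17)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        _, var = pca_clr(m)
        total = m.to_numpy().var(axis=0, ddof=1).sum()
        assert var.sum() == pytest.approx(total)

    def test_matches_eigendecomposition_oracle(self):
        m = pd.DataFrame(
            [[2.0, 0.0, 1.0], [0.0, 1.0, -1.0], [1.0, 2.0, 0.5]],
            index=["s1", "s2", "s3"],
        )
        coords, var = pca_clr(m)
        X = m.to_numpy() - m.to_numpy().mean(axis=0)
        evals = np.linalg.eigvalsh(np.cov(X.T))[::-1]
        assert var[: len(evals)] == pytest.approx(evals[: var.size], abs=1e-9)
        # coordinate geometry: pairwise distances are preserved
        from scipy.spatial.distance import pdist

        assert pdist(coords.to_numpy()) == pytest.approx(pdist(X), abs=1e-9)

    def test_matches_sklearn_up_to_sign(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(18)
        m = pd.DataFrame(rng.normal(size=(8, 5)))
        coords, _ = pca_clr(m)
        sk = PCA().fit_transform(m.to_numpy())
        for k in range(sk.shape[1]):
            col = coords.to_numpy()[:, k]
            assert np.allclose(col, sk[:, k], atol=1e-8) or np.allclose(
                col, -sk[:, k], atol=1e-8
            )

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            pca_clr(pd.DataFrame([[1.0, 2.0]]))
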