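import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphnet.errors import DegenerateRangeError, ValidationError
from morphnet.similarity import (
    build_similarity_matrix,
    distribution_similarity,
    pair_frequencies,
    pooled_bin_edges,
)

positive_floats = st.floats(0.1, 100.0, allow_nan=False)
multisets = st.lists(positive_floats, min_size=2, max_size=40).map(np.array)


class TestPooledBinEdges:
    def test_figure_worked_example_bin_width(self):
        """Pooled range 5.4-66.4 over 30 bins gives width 2.03."""
        edges = pooled_bin_edges([5.4, 50.0], [30.0, 66.4], n_bins=30)
        width = edges[1] - edges[0]
        assert width == pytest.approx((66.4 - 5.4) / 30)
        assert round(width, 2) == 2.03

    def test_unit_width_edges(self):
        edges = pooled_bin_edges([0.0, 30.0], [10.0], n_bins=30)
        np.testing.assert_allclose(edges, np.arange(31.0))

    def test_degenerate_range_signals(self):
        with pytest.raises(DegenerateRangeError):
            pooled_bin_edges([7.0], [7.0, 7.0])

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValidationError):
            pooled_bin_edges([], [1.0])


class TestPairFrequencies:
    def test_direct_counts(self):
        hist = pair_frequencies([0.5, 1.5, 1.6], [0.1, 1.9, 1.9], np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(hist.freq_a, [1, 2])
        np.testing.assert_array_equal(hist.freq_b, [1, 2])

    def test_value_at_last_edge_in_final_bin(self):
        hist = pair_frequencies([2.0], [0.0, 1.0], np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(hist.freq_a, [0, 1])

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValidationError):
            pair_frequencies([5.0], [0.5], np.array([0.0, 1.0, 2.0]))

    @given(a=multisets, b=multisets)
    def test_counts_conserve_multiset_sizes(self, a, b):
        """Every value lands in exactly one bin (brute-force assignment check)."""
        if min(a.min(), b.min()) == max(a.max(), b.max()):
            return
        edges = pooled_bin_edges(a, b, n_bins=10)
        hist = pair_frequencies(a, b, edges)
        assert hist.freq_a.sum() == len(a)
        assert hist.freq_b.sum() == len(b)
        # independent per-value bin assignment
        for v in a:
            k = np.searchsorted(edges, v, side="right") - 1
            k = min(k, 9)
            assert edges[k] <= v <= edges[k + 1]


class TestDistributionSimilarity:
    def test_identical_multisets_give_unit_similarity(self):
        values = np.array([1.0, 2.0, 2.5, 7.0, 9.0])
        for n_bins in (2, 5, 30):
            assert distribution_similarity(values, values, n_bins) == pytest.approx(1.0)

    def test_hand_evaluated_pearson(self):
        """freq_a=(3,1,0,0) vs freq_b=(0,0,1,3) -> r = -2/3 by hand."""
        a = np.array([0.5, 0.5, 0.5, 1.5])
        b = np.array([2.5, 3.5, 3.5, 3.5])
        edges = pooled_bin_edges(a, b, n_bins=4)
        hist = pair_frequencies(a, b, edges)
        np.testing.assert_array_equal(hist.freq_a, [3, 1, 0, 0])
        np.testing.assert_array_equal(hist.freq_b, [0, 0, 1, 3])
        r = distribution_similarity(a, b, n_bins=4)
        assert r == pytest.approx(-2.0 / 3.0)
        # cross-check with an independent correlation routine
        from scipy.stats import pearsonr

        assert r == pytest.approx(pearsonr(hist.freq_a, hist.freq_b).statistic)

    @given(a=multisets, b=multisets)
    def test_symmetry(self, a, b):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert distribution_similarity(a, b) == pytest.approx(
                distribution_similarity(b, a)
            )

    def test_proportion_invariance(self, rng):
        """Pearson of counts equals Pearson of proportions."""
        a = rng.lognormal(3.0, 0.4, 80)
        b = rng.lognormal(3.2, 0.5, 50)
        edges = pooled_bin_edges(a, b)
        hist = pair_frequencies(a, b, edges)
        r_counts = np.corrcoef(hist.freq_a, hist.freq_b)[0, 1]
        r_props = np.corrcoef(hist.freq_a / len(a), hist.freq_b / len(b))[0, 1]
        assert r_counts == pytest.approx(r_props, abs=1e-12)
        assert distribution_similarity(a, b) == pytest.approx(r_counts)

    def test_joint_scaling_invariance(self, rng):
        """Doubling all values in both parcels rescales edges, not counts."""
        a = rng.lognormal(3.0, 0.4, 60)
        b = rng.lognormal(3.5, 0.3, 70)
        assert distribution_similarity(2 * a, 2 * b) == pytest.approx(
            distribution_similarity(a, b)
        )

    def test_degenerate_cases_map_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert distribution_similarity([3.0, 3.0], [3.0]) == 0.0
        # constant non-trivial frequency pattern: single repeated value in a
        # two-value pooled range puts everything in one bin per parcel, but a
        # uniform spread across every bin has zero variance too
        with pytest.warns(UserWarning, match="constant"):
            a = np.array([0.5, 1.5, 2.5, 3.5])  # one per bin -> constant vector
            b = np.array([0.5, 0.5, 3.5, 0.6])
            distribution_similarity(a, b, n_bins=4)


class TestBuildSimilarityMatrix:
    def test_matrix_matches_pairwise_calls(self, toy_subject):
        sim = build_similarity_matrix(toy_subject, "volume")
        labels = sim.labels
        for i in range(3):
            for j in range(i + 1, 3):
                expected = distribution_similarity(
                    toy_subject.values[labels[i]]["volume"],
                    toy_subject.values[labels[j]]["volume"],
                )
                assert sim.matrix[i, j] == pytest.approx(expected)

    def test_exactly_symmetric_unit_diagonal(self, toy_subject):
        sim = build_similarity_matrix(toy_subject, "area")
        assert (sim.matrix == sim.matrix.T).all()
        np.testing.assert_array_equal(np.diag(sim.matrix), 1.0)
        assert np.abs(sim.matrix).max() <= 1.0

    def test_same_distribution_pair_has_highest_similarity(self, rng):
        """Two parcels drawn from one distribution out-correlate a shifted one."""
        from morphnet.morphometry_io import Parcellation, SubjectMorphometry

        wins = 0
        for rep in range(20):
            gen = np.random.default_rng(1000 + rep)
            base = {"loc": 3.0, "scale": 0.3}
            values = {
                "P(lh)": {"volume": gen.lognormal(base["loc"], base["scale"], 200)},
                "Q(lh)": {"volume": gen.lognormal(base["loc"], base["scale"], 200)},
                "R(rh)": {"volume": gen.lognormal(base["loc"] + 2.0, base["scale"], 200)},
            }
            for v in values.values():
                v["area"] = v["volume"]
                v["thickness"] = v["volume"]
            sm = SubjectMorphometry(
                "x", Parcellation(("P(lh)", "Q(lh)", "R(rh)")), values
            )
            mat = build_similarity_matrix(sm, "volume").matrix
            wins += mat[0, 1] > max(mat[0, 2], mat[1, 2])
        assert wins >= 18

    def test_permuting_parcels_permutes_matrix(self, toy_subject):
        from morphnet.morphometry_io import Parcellation, SubjectMorphometry

        order = ("C(rh)", "A(lh)", "B(lh)")
        permuted = SubjectMorphometry(
            "toy",
            Parcellation(order),
            {p: toy_subject.values[p] for p in order},
        )
        sim = build_similarity_matrix(toy_subject, "volume")
        sim_p = build_similarity_matrix(permuted, "volume")
        idx = [toy_subject.parcellation.labels.index(p) for p in order]
        np.testing.assert_allclose(sim_p.matrix, sim.matrix[np.ix_(idx, idx)])
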