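import math

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from snpnets import (
    MEASURES,
    AssociationMap,
    build_all_networks,
    build_network,
    distance_to_similarity,
    raw_score,
)
from conftest import normalized_map


def oracle_score(x, y, measure):
    """Direct textbook formulas, independent of the implementation path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if measure == "pearson":
        xc, yc = x - x.mean(), y - y.mean()
        return (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
    if measure == "spearman":
        def ranks(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            for val in np.unique(v):  # average ranks on ties
                m = v == val
                r[m] = r[m].mean()
            return r
        return oracle_score(ranks(x), ranks(y), "pearson")
    if measure == "manhattan":
        return float(sum(abs(a - b) for a, b in zip(x, y)))
    if measure == "euclidean":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if measure == "cosine":
        return float((x * y).sum() / (math.sqrt((x**2).sum()) * math.sqrt((y**2).sum())))
    raise ValueError(measure)


class TestRawScore:
    def test_direction_only_measures_see_parallel_vectors_as_identical(self):
        """(1,2,3) and (0.001,0.002,0.003) differ 1000-fold in magnitude but
        point the same way: correlation and cosine scores are exactly 1."""
        x, y = np.array([1.0, 2.0, 3.0]), np.array([0.001, 0.002, 0.003])
        assert raw_score(x, y, "pearson") == pytest.approx(1.0, abs=1e-15)
        assert raw_score(x, y, "spearman") == pytest.approx(1.0, abs=1e-15)
        assert raw_score(x, y, "cosine") == pytest.approx(1.0, abs=1e-15)

    def test_identical_vectors_have_zero_distance(self):
        x = np.array([0.3, 1.2, 4.0])
        assert raw_score(x, x, "euclidean") == 0.0
        assert raw_score(x, x, "manhattan") == 0.0

    @pytest.mark.parametrize("measure", MEASURES)
    def test_matches_direct_formula_oracle(self, rng, measure):
        for _ in range(10):
            x = rng.normal(size=116)
            y = rng.normal(size=116)
            assert raw_score(x, y, measure) == pytest.approx(
                oracle_score(x, y, measure), abs=1e-10
            )

    def test_undefined_cases_return_nan(self):
        const = np.ones(5)
        zero = np.zeros(5)
        other = np.arange(5.0)
        assert math.isnan(raw_score(const, other, "pearson"))
        assert math.isnan(raw_score(const, other, "spearman"))
        assert math.isnan(raw_score(zero, other, "cosine"))

    def test_scale_invariance_split(self, rng):
        """Scaling one vector leaves direction measures unchanged but changes
        the distance measures."""
        x, y = rng.normal(size=20), rng.normal(size=20)
        for measure in ("pearson", "spearman", "cosine"):
            assert raw_score(3.7 * x, y, measure) == pytest.approx(
                raw_score(x, y, measure), abs=1e-12
            )
        for measure in ("manhattan", "euclidean"):
            assert raw_score(3.7 * x, y, measure) != pytest.approx(
                raw_score(x, y, measure), abs=1e-6
            )


class TestDistanceToSimilarity:
    def test_extremes(self, rng):
        d = squareform(rng.uniform(1.0, 5.0, size=15))  # 6x6, zero diagonal
        s = distance_to_similarity(d)
        assert s[0, 0] == 1.0  # d = dmin = 0
        imax = np.unravel_index(np.argmax(d), d.shape)
        # at d = dmax the exponent is -0.5 * 3^2 since sigma = dmax/3
        assert s[imax] == pytest.approx(math.exp(-4.5), abs=1e-12)

    def test_matches_formula(self, rng):
        d = squareform(rng.uniform(0.5, 2.0, size=10))
        s = distance_to_similarity(d)
        dmin, dmax = d.min(), d.max()
        sigma = (dmax - dmin) / 3
        expected = np.exp(-0.5 * ((d - dmin) / sigma) ** 2)
        np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_all_equal_distances_map_to_one(self):
        assert (distance_to_similarity(np.zeros((3, 3))) == 1.0).all()

    def test_strictly_decreasing_in_distance(self, rng):
        d = squareform(rng.uniform(0.1, 3.0, size=45))
        s = distance_to_similarity(d)
        flat_d, flat_s = d.ravel(), s.ravel()
        order = np.argsort(flat_d)
        diffs_d = np.diff(flat_d[order])
        diffs_s = np.diff(flat_s[order])
        assert (diffs_s[diffs_d > 0] < 0).all()


class TestDistanceToSimilarityProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
            min_size=6,
            max_size=6,  # the upper triangle of a 4x4 distance matrix
        )
    )
    def test_rbf_range_and_center(self, offdiag):
        """For any nonnegative distances: similarities lie in (0, 1], the
        zero diagonal maps to exactly 1, and larger distances never map to
        larger similarities."""
        d = squareform(np.array(offdiag))
        s = distance_to_similarity(d)
        assert (s > 0).all() and (s <= 1).all()
        assert (np.diag(s) == 1.0).all()
        order = np.argsort(d.ravel())
        assert (np.diff(s.ravel()[order]) <= 1e-12).all()


class TestBuildNetwork:
    def test_duplicate_rows_have_weight_one_under_all_measures(self):
        values = np.array([[0.6, 0.8, 0.0], [0.6, 0.8, 0.0], [0.0, 0.6, 0.8]])
        assoc = AssociationMap(["a", "b", "c"], ["r1", "r2", "r3"], values, normalized=True)
        for measure in MEASURES:
            net = build_network(assoc, measure)
            assert net.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negative_correlation_becomes_absolute_value(self):
        # rows anticorrelated: pearson = -1 -> weight 1
        values = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5]])
        assoc = AssociationMap(["a", "b"], ["r1", "r2", "r3"], values, normalized=True)
        net = build_network(assoc, "pearson")
        r = raw_score(values[0], values[1], "pearson")
        assert r < 0
        assert net.weights[0, 1] == pytest.approx(abs(r), abs=1e-12)

    @pytest.mark.parametrize("measure", MEASURES)
    def test_invariants_symmetric_unit_interval_unit_diagonal(self, rng, measure):
        net = build_network(normalized_map(rng, 12, 9), measure)
        w = net.weights
        np.testing.assert_allclose(w, w.T, atol=1e-12)
        assert w.min() >= 0 and w.max() <= 1
        np.testing.assert_array_equal(np.diag(w), 1.0)

    def test_matches_raw_score_pairwise(self, rng):
        assoc = normalized_map(rng, 6, 8)
        for measure in ("pearson", "spearman", "cosine"):
            net = build_network(assoc, measure)
            for i in range(6):
                for j in range(i + 1, 6):
                    expected = abs(raw_score(assoc.values[i], assoc.values[j], measure))
                    assert net.weights[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_row_gets_weight_zero(self):
        values = np.array([[0.5, 0.5, 0.5], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assoc = AssociationMap(["a", "b", "c"], ["r1", "r2", "r3"], values, normalized=True)
        net = build_network(assoc, "pearson")
        assert net.weights[0, 1] == 0.0 and net.weights[0, 2] == 0.0
        assert net.weights[0, 0] == 1.0  # diagonal forced to 1

    def test_requires_normalized_map(self, rng):
        values = np.abs(rng.normal(size=(4, 5)))
        assoc = AssociationMap([f"s{i}" for i in range(4)], [f"r{j}" for j in range(5)], values)
        with pytest.raises(ValueError, match="normalized"):
            build_network(assoc, "cosine")


class TestBuildAllNetworks:
    def test_five_networks_consistent_order(self, rng):
        assoc = normalized_map(rng, 5, 7)
        nets = build_all_networks(assoc)
        assert [n.measure for n in nets] == list(MEASURES)
        for n in nets:
            assert n.snp_ids == assoc.snp_ids

    def test_equals_componentwise_builds(self, rng):
        assoc = normalized_map(rng, 7, 11)
        nets = build_all_networks(assoc)
        for net in nets:
            single = build_network(assoc, net.measure)
            np.testing.assert_array_equal(net.weights, single.weights)
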