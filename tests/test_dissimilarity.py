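import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from gcfpool import (
    dissimilarity_index,
    dissimilarity_table,
    distance_matrix,
    hierarchical_cluster,
    normalize_within_level,
    pcoa,
    standardize_effects,
)


def frame(values, index=None, columns=None):
    values = np.asarray(values, dtype=float)
    index = index or [f"f{i}" for i in range(values.shape[0])]
    columns = columns or [f"r{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=index, columns=columns)


class TestStandardize:
    def test_symmetric_three_point_column(self):
        out = standardize_effects(frame([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = standardize_effects(frame([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0]]))
        assert (out.iloc[:, 0] == 0).all()

    def test_moments_recomputed_independently(self):
        rng = np.random.default_rng(0)
        out = standardize_effects(frame(rng.normal(size=(12, 7))))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_factor_raises(self):
        with pytest.raises(ValueError, match="two factors"):
            standardize_effects(frame([[1.0, 2.0]]))


class TestDistanceMatrix:
    def test_three_four_five(self):
        dm = distance_matrix(frame([[0.0, 0.0], [3.0, 4.0]]))
        assert dm.iloc[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        dm = distance_matrix(frame([[1.0, 2.0], [1.0, 2.0]]))
        assert dm.iloc[0, 1] == 0.0

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(1)
        m = frame(rng.normal(size=(12, 7)))
        dm = distance_matrix(m)
        for a, b in itertools.combinations(range(12), 2):
            expected = np.sqrt(((m.iloc[a] - m.iloc[b]) ** 2).sum())
            assert dm.iloc[a, b] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(dm.to_numpy(), dm.to_numpy().T)
        assert (np.diag(dm.to_numpy()) == 0).all()


@pytest.fixture(scope="module")
def dm():
    rng = np.random.default_rng(2)
    return distance_matrix(frame(rng.normal(size=(8, 5))))


class TestDissimilarityIndex:

    def test_two_factor_equals_matrix_entry(self, dm):
        assert dissimilarity_index(("f0", "f3"), dm) == dm.loc["f0", "f3"]

    def test_unit_distances_three_members(self):
        d = frame(np.ones((3, 3)) - np.eye(3), index=list("abc"), columns=list("abc"))
        assert dissimilarity_index(("a", "b", "c"), d) == pytest.approx(3.0)

    def test_five_members_match_pair_enumeration_oracle(self, dm):
        members = ("f0", "f2", "f4", "f5", "f7")
        expected = sum(dm.loc[a, b] for a, b in itertools.combinations(members, 2))
        assert len(list(itertools.combinations(members, 2))) == 10
        assert dissimilarity_index(members, dm) == pytest.approx(expected, rel=1e-12)

    def test_unknown_member_raises(self, dm):
        with pytest.raises(KeyError, match="zz"):
            dissimilarity_index(("f0", "zz"), dm)

    def test_monotone_under_adding_member(self, dm):
        base = ("f0", "f1", "f2")
        assert dissimilarity_index(base + ("f3",), dm) >= dissimilarity_index(base, dm)

    def test_raw_scale_grows_with_level(self, pool, noisy_small):
        _, design, _ = noisy_small
        rng = np.random.default_rng(3)
        dm = distance_matrix(frame(rng.normal(size=(12, 7)), index=list(pool.factors)))
        di = dissimilarity_table(design, dm)
        means = di.groupby("level")["di_raw"].mean()
        assert means.loc[2] < means.loc[5]


class TestNormalization:
    def test_simple_range(self):
        df = pd.DataFrame({"treatment_id": list("xyz"), "level": 2, "di_raw": [2.0, 4.0, 6.0]})
        out = normalize_within_level(df)
        np.testing.assert_allclose(out["di_norm"], [0.0, 0.5, 1.0])

    def test_zero_range_warns(self):
        df = pd.DataFrame({"treatment_id": list("xy"), "level": 2, "di_raw": [3.0, 3.0]})
        with pytest.warns(RuntimeWarning, match="zero range"):
            out = normalize_within_level(df)
        assert (out["di_norm"] == 0).all()

    def test_extrema_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(1, 9, size=20)
        df = pd.DataFrame({"treatment_id": range(20), "level": 5, "di_raw": raw})
        out = normalize_within_level(df)
        assert out["di_norm"].min() == 0.0 and out["di_norm"].max() == 1.0
        scaled = df.assign(di_raw=3.0 * raw + 7.0)
        np.testing.assert_allclose(
            normalize_within_level(scaled)["di_norm"], out["di_norm"], atol=1e-12
        )


class TestPCoA:
    def test_collinear_points_single_axis(self):
        pts = frame([[0.0], [1.0], [3.0], [6.0]])
        dm = distance_matrix(pts)
        _, fractions = pcoa(dm, n_axes=3)
        assert fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_planar_configuration_two_axes_and_roundtrip(self):
        rng = np.random.default_rng(5)
        pts = frame(rng.normal(size=(7, 2)))
        dm = distance_matrix(pts)
        coords, fractions = pcoa(dm, n_axes=2)
        assert fractions[:2].sum() == pytest.approx(1.0, abs=1e-9)
        # recovered inter-point distances reproduce the input
        rec = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(rec, dm.to_numpy(), atol=1e-8)


class TestClustering:
    def test_two_factors_single_merge(self):
        d = frame([[0.0, 2.5], [2.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        Z, newick = hierarchical_cluster(d)
        assert Z.shape == (1, 4)
        # UPGMA merge height is d/2 per branch; total tip-to-tip distance = d
        tree = TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == {"a", "b"}
        assert tree.tip_tip_distances().data.max() == pytest.approx(2.5)

    def test_close_pair_merges_first(self):
        labels = list("abc")
        d = frame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], index=labels, columns=labels
        )
        Z, _ = hierarchical_cluster(d)
        assert sorted(Z[0, :2]) == [0, 1] and Z[0, 2] == pytest.approx(1.0)

    def test_complete_linkage_matches_naive_agglomeration(self):
        rng = np.random.default_rng(6)
        pts = frame(rng.normal(size=(6, 4)))
        dm = distance_matrix(pts)
        Z, _ = hierarchical_cluster(dm, linkage="complete")
        got = squareform(cophenet(Z))

        # naive O(n^3) complete-linkage oracle building cophenetic distances
        clusters = {i: {i} for i in range(6)}
        coph = np.zeros((6, 6))
        d = dm.to_numpy()
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(sorted(clusters), 2):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[0]:
                    best = (h, a, b)
            h, a, b = best
            for i in clusters[a]:
                for j in clusters[b]:
                    coph[i, j] = coph[j, i] = h
            clusters[a] = clusters[a] | clusters[b]
            del clusters[b]
        np.testing.assert_allclose(got, coph, rtol=1e-10)
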