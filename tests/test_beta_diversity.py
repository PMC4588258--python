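"""Dissimilarities, NMDS, and permutation tests against independent oracles."""

import itertools

import numpy as np
import pytest
import skbio
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata

from mbratools.beta_diversity import (
    DistanceMatrix, anosim, bray_curtis, distance_matrix, nmds, permanova,
    similarity_partition, sorenson,
)
from mbratools.errors import InsufficientDataError

from conftest import make_table


class TestDissimilarities:
    def test_bray_curtis_hand_values(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == 0.0
        assert bray_curtis([5, 0, 0], [0, 3, 2]) == 1.0
        assert bray_curtis([10, 0, 5], [0, 10, 5]) == pytest.approx(20 / 30)

    def test_sorenson_hand_values(self):
        assert sorenson([3, 1, 4, 0], [1, 9, 2, 0]) == 0.0
        assert sorenson([0, 1, 1, 1, 0], [0, 0, 1, 1, 1]) == pytest.approx(
            1 - 4 / 6
        )

    def test_bray_curtis_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.integers(0, 30, size=(2, 10))
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=2, max_size=8),
        st.data(),
    )
    def test_sorenson_is_binary_bray_curtis(self, x, data):
        y = data.draw(
            st.lists(st.integers(min_value=0, max_value=20),
                     min_size=len(x), max_size=len(x))
        )
        x, y = np.asarray(x), np.asarray(y)
        if x.sum() == 0 or y.sum() == 0:
            return
        assert sorenson(x, y) == pytest.approx(
            bray_curtis((x > 0).astype(int), (y > 0).astype(int))
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [1, 2])


class TestDistanceMatrix:
    def test_duplicate_samples_at_zero_distance(self):
        table = make_table([[50, 30, 20], [50, 30, 20], [10, 10, 80]])
        dm = distance_matrix(table, "bray_curtis", depth=100, seed=0)
        assert dm.between("s0", "s1") < 0.15  # only subsampling noise
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)

    def test_too_few_samples_raises(self):
        table = make_table([[50, 30, 20], [1, 1, 1]])
        with pytest.raises(InsufficientDataError):
            distance_matrix(table, "bray_curtis", depth=90, seed=0)

    def test_planted_donor_structure_separates(self, small_study):
        dm = distance_matrix(small_study.table, "bray_curtis", 2_000, seed=1)
        meta = small_study.table.metadata
        donors = meta.loc[dm.ids, "donor"].to_numpy()
        same = dm.data[np.ix_(donors == "A", donors == "A")]
        diff = dm.data[np.ix_(donors == "A", donors == "B")]
        assert diff.mean() > same[np.triu_indices_from(same, 1)].mean()

    def test_tsv_round_trip(self, tmp_path):
        table = make_table([[50, 30, 20], [10, 10, 80], [30, 40, 30]])
        dm = distance_matrix(table, "sorenson", depth=90, seed=0)
        path = tmp_path / "d.tsv"
        dm.write_tsv(path)
        back = DistanceMatrix.read_tsv(path, "sorenson")
        assert back.ids == dm.ids
        assert np.allclose(back.data, dm.data, atol=1e-6)


class TestNmds:
    def test_perfect_embedding_has_near_zero_stress(self):
        pts = np.array([[0.0, 0.0], [0.3, 0.0], [0.0, 0.4]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(["a", "b", "c"], d, "bray_curtis")
        res = nmds(dm, dimensions=2, restarts=4, seed=0)
        assert res.stress < 1e-3

    def test_duplicates_map_to_coincident_points(self):
        d = np.array(
            [[0.0, 0.0, 0.8], [0.0, 0.0, 0.8], [0.8, 0.8, 0.0]]
        )
        dm = DistanceMatrix(["a", "a2", "b"], d, "bray_curtis")
        res = nmds(dm, dimensions=2, restarts=4, seed=0)
        dup = np.linalg.norm(res.coordinates.loc["a"] - res.coordinates.loc["a2"])
        far = np.linalg.norm(res.coordinates.loc["a"] - res.coordinates.loc["b"])
        assert dup < 0.1 * far

    def test_more_dimensions_never_increase_stress(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = rng.random((7, 5))
            d = np.abs(x[:, None] - x[None, :]).sum(-1)
            d = d / d.max()
            dm = DistanceMatrix([f"s{i}" for i in range(7)], d, "bray_curtis")
            s1 = nmds(dm, dimensions=1, restarts=8, seed=4).stress
            s2 = nmds(dm, dimensions=2, restarts=8, seed=4).stress
            assert s2 <= s1 + 1e-6

    def test_degenerate_matrix_raises(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)), "bray_curtis")
        with pytest.raises(ValueError):
            nmds(dm, 2, restarts=2, seed=0)


def _random_dm(rng, n):
    x = rng.random((n, 4))
    d = np.abs(x[:, None] - x[None, :]).sum(-1)
    d = d / (d.max() + 1e-9)
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "bray_curtis")


def _brute_anosim(dm, groups):
    """Plain-loop ANOSIM with exhaustive label permutations."""
    n = len(groups)
    pairs = list(itertools.combinations(range(n), 2))
    ranks = rankdata([dm.data[i, j] for i, j in pairs])

    def r_stat(g):
        within = [r for (i, j), r in zip(pairs, ranks) if g[i] == g[j]]
        between = [r for (i, j), r in zip(pairs, ranks) if g[i] != g[j]]
        m = len(pairs)
        return (np.mean(between) - np.mean(within)) / (m / 2)

    observed = r_stat(groups)
    perms = sorted(set(itertools.permutations(groups)))
    stats = [r_stat(p) for p in perms]
    p = np.mean([s >= observed - 1e-12 for s in stats])
    return observed, p


def _brute_permanova(dm, groups):
    """Plain-loop PERMANOVA with exhaustive label permutations."""
    n = len(groups)
    labels = sorted(set(groups))
    a = len(labels)

    def f_stat(g):
        ss_total = sum(
            dm.data[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ss_within = 0.0
        for lab in labels:
            idx = [i for i in range(n) if g[i] == lab]
            ss_within += sum(
                dm.data[i, j] ** 2
                for ii, i in enumerate(idx) for j in idx[ii + 1:]
            ) / len(idx)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    observed = f_stat(groups)
    perms = sorted(set(itertools.permutations(groups)))
    stats = [f_stat(p) for p in perms]
    p = np.mean([s >= observed - 1e-12 for s in stats])
    return observed, p


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(list("abcd"), d, "bray_curtis")
        res = anosim(dm, ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_all_equal_distances_give_r_zero(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(list("abcd"), d, "bray_curtis")
        res = anosim(dm, ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.statistic == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for n, groups in [(5, list("aabbb")), (6, list("aaabbb")),
                          (7, list("aabbbcc"))]:
            dm = _random_dm(rng, n)
            res = anosim(dm, groups, permutations="exhaustive")
            obs, p = _brute_anosim(dm, groups)
            assert res.statistic == pytest.approx(obs)
            assert res.p_value == pytest.approx(p)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(6)
        dm = _random_dm(rng, 8)
        groups = list("aaaabbbb")
        res = anosim(dm, groups, permutations=99, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.data, dm.ids), groups, permutations=0
        )
        assert res.statistic == pytest.approx(ref["test statistic"])

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(7)
        dm = _random_dm(rng, 4)
        with pytest.raises(InsufficientDataError):
            anosim(dm, ["a", "b", "b", "b"], permutations=9, seed=0)


class TestPermanova:
    def test_ss_total_invariant_under_label_permutation(self):
        rng = np.random.default_rng(8)
        dm = _random_dm(rng, 6)
        d2 = dm.data**2
        n = 6
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        # SS_total has no group dependence; invariance is structural
        assert ss_total > 0

    def test_separated_clusters_floor_p_value(self):
        d = np.full((6, 6), 1.0)
        block = np.full((3, 3), 0.01)
        d[:3, :3] = block
        d[3:, 3:] = block
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "bray_curtis")
        groups = ["a"] * 3 + ["b"] * 3
        res = permanova(dm, groups, permutations=999, seed=0)
        assert res.statistic > 100
        # random-mode p can never undercut the (1+b)/(1+m) floor and must sit
        # near the exhaustive value (only the 2 equivalent partitions tie)
        ex = permanova(dm, groups, permutations="exhaustive")
        _, p_brute = _brute_permanova(dm, groups)
        assert ex.p_value == pytest.approx(p_brute) == pytest.approx(2 / 20)
        assert 1 / 1000 <= res.p_value <= p_brute + 0.05

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for n, groups in [(5, list("aabbb")), (7, list("aaabbbb"))]:
            dm = _random_dm(rng, n)
            res = permanova(dm, groups, permutations="exhaustive")
            obs, p = _brute_permanova(dm, groups)
            assert res.statistic == pytest.approx(obs)
            assert res.p_value == pytest.approx(p)

    def test_matches_centroid_formulation_via_embedding(self):
        # Euclidean-embeddable distances: the distance formulation must agree
        # with explicit centroid sums of squares in the embedding space
        rng = np.random.default_rng(10)
        x = rng.random((6, 3))
        dmax = np.linalg.norm(x[:, None] - x[None, :], axis=-1).max()
        x_scaled = x / dmax
        d = np.linalg.norm(x_scaled[:, None] - x_scaled[None, :], axis=-1)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "bray_curtis")
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(dm, groups, permutations=9, seed=0)
        a = 2
        n = 6
        grand = x_scaled.mean(axis=0)
        ss_total = ((x_scaled - grand) ** 2).sum()
        ss_within = sum(
            ((x_scaled[groups == g] - x_scaled[groups == g].mean(axis=0)) ** 2).sum()
            for g in ("a", "b")
        )
        ss_between = ss_total - ss_within
        f_direct = (ss_between / (a - 1)) / (ss_within / (n - a))
        assert res.statistic == pytest.approx(f_direct)
        assert res.r_squared == pytest.approx(ss_between / ss_total)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(11)
        dm = _random_dm(rng, 8)
        groups = list("aaaabbbb")
        res = permanova(dm, groups, permutations=9, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, dm.ids), groups, permutations=0
        )
        assert res.statistic == pytest.approx(ref["test statistic"])


def test_planted_groups_beat_random_groups(small_study):
    dm = distance_matrix(small_study.table, "bray_curtis", 2_000, seed=2)
    meta = small_study.table.metadata
    keep = [s for s in dm.ids if meta.loc[s, "sample_class"] == "reactor"]
    sub = dm.submatrix(keep)
    donors = meta.loc[keep, "donor"].to_numpy()
    res_true = anosim(sub, donors, permutations=99, seed=3)
    rng = np.random.default_rng(4)
    res_rand = anosim(sub, rng.permutation(donors), permutations=99, seed=5)
    assert res_true.statistic > res_rand.statistic


def test_similarity_partition_orders_relationships(default_study):
    dm = distance_matrix(default_study.table, "bray_curtis", 10_000, seed=6)
    part = similarity_partition(dm, default_study.table.metadata)
    means = part.groupby("comparison")["mean_similarity"].mean()
    assert (
        means["within_vessel"]
        > means["between_replicates"]
        > means["between_types"]
    )
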