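import itertools

import numpy as np
import pytest

from famevo.expression import (
    Dendrogram,
    average_linkage,
    correlation_distance,
    cut_clusters,
    log_transform,
    pair_expression_divergence,
)
from famevo.io import ExpressionMatrix
from famevo.phylo import DistanceMatrix
from famevo.simulate import simulate_expression_matrix


def brute_force_linkage(values):
    """Exhaustive average-linkage oracle: recompute every cluster pair's
    average original-item distance at each step."""
    n = values.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for ci, cj in itertools.combinations(sorted(clusters), 2):
            height = float(
                np.mean([values[a, b] for a in clusters[ci] for b in clusters[cj]])
            )
            key = (height, ci, cj)
            if best is None or key < best:
                best = key
        height, ci, cj = best
        merges.append((ci, cj, height))
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        next_id += 1
    return merges


def _matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = [f"t{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, tissues, values)


class TestLogTransform:
    def test_values(self):
        m = log_transform(_matrix([[0, 7, 3]]))
        assert m.values[0] == pytest.approx([0.0, 3.0, 2.0])

    def test_monotone_per_row(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(0, 100, size=(3, 8)))
        logged = log_transform(m)
        for raw, lg in zip(m.values, logged.values):
            assert np.array_equal(np.argsort(raw), np.argsort(lg))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(_matrix([[-1.0, 2.0]]))


class TestCorrelationDistance:
    def test_identical_rows_zero(self):
        d = correlation_distance(_matrix([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_rows_two(self):
        d = correlation_distance(_matrix([[1, 2, 3], [3, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_shift_invariance(self):
        d = correlation_distance(_matrix([[1, 2, 3], [6, 7, 8]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_flagged(self):
        with pytest.raises(ValueError, match="g1"):
            correlation_distance(_matrix([[1, 2, 3], [5, 5, 5]]))

    def test_uncentered_variant(self):
        d = correlation_distance(_matrix([[1, 2, 3], [2, 4, 6]]), centered=False)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestAverageLinkage:
    def test_simple_three_item_example(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]),
        )
        dendro = average_linkage(d)
        assert dendro.merges[0] == (0, 1, pytest.approx(0.1))
        assert dendro.merges[1][2] == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        raw = rng.uniform(0.1, 2.0, size=(n, n))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        d = DistanceMatrix([f"i{k}" for k in range(n)], values)
        assert list(average_linkage(d).merges) == [
            (i, j, pytest.approx(h)) for i, j, h in brute_force_linkage(values)
        ]

    def test_matches_scipy_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(123)
        raw = rng.uniform(0.1, 2.0, size=(8, 8))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        d = DistanceMatrix([f"i{k}" for k in range(8)], values)
        mine = sorted(h for _, _, h in average_linkage(d).merges)
        theirs = sorted(linkage(squareform(values), method="average")[:, 2])
        assert mine == pytest.approx(theirs)

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.1, 2.0, size=(6, 6))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        perm = rng.permutation(6)
        d1 = DistanceMatrix([f"i{k}" for k in range(6)], values)
        d2 = DistanceMatrix(
            [f"i{k}" for k in perm], values[np.ix_(perm, perm)]
        )
        h1 = sorted(h for *_, h in average_linkage(d1).merges)
        h2 = sorted(h for *_, h in average_linkage(d2).merges)
        assert h1 == pytest.approx(h2)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            average_linkage(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestCutAndRecovery:
    def test_two_planted_clusters_recovered(self):
        m, labels = simulate_expression_matrix(
            10,
            6,
            [(5, [9, 8, 7, 2, 1, 1]), (5, [1, 1, 2, 7, 8, 9])],
            noise_sd=0.3,
            seed=4,
        )
        dendro = average_linkage(correlation_distance(log_transform(m)))
        cut = cut_clusters(dendro, k=2)
        # same partition as planted labels, up to label swap
        groups = {}
        for planted, got in zip(labels, cut):
            groups.setdefault(planted, set()).add(got)
        assert all(len(v) == 1 for v in groups.values())
        assert groups[0] != groups[1]

    def test_cut_bounds_checked(self):
        dendro = Dendrogram(2, ((0, 1, 0.5),), (0, 1))
        with pytest.raises(ValueError):
            cut_clusters(dendro, 3)


class TestPairDivergence:
    def test_identical_profiles_not_divergent(self):
        m = _matrix([[1, 5, 9], [1, 5, 9]], genes=["a", "b"])
        report = pair_expression_divergence([("a", "b")], m)
        assert report.loc[0, "correlation"] == pytest.approx(1.0)
        assert not report.loc[0, "divergent"]

    def test_anticorrelated_divergent(self):
        m = _matrix([[1, 5, 9], [9, 5, 1]], genes=["a", "b"])
        report = pair_expression_divergence([("a", "b")], m)
        assert report.loc[0, "correlation"] == pytest.approx(-1.0)
        assert report.loc[0, "divergent"]

    def test_planted_similar_and_divergent_pairs(self):
        rng = np.random.default_rng(6)
        profile = np.array([8.0, 7.0, 2.0, 1.0])
        m = _matrix(
            np.vstack(
                [
                    profile + rng.normal(0, 0.2, 4),
                    profile + rng.normal(0, 0.2, 4),
                    profile[::-1] + rng.normal(0, 0.2, 4),
                ]
            ),
            genes=["a", "b", "c"],
        )
        report = pair_expression_divergence([("a", "b"), ("a", "c")], m)
        assert list(report["divergent"]) == [False, True]

    def test_absent_gene_named_in_error(self):
        m = _matrix([[1, 2, 3]], genes=["a"])
        with pytest.raises(ValueError, match="zz"):
            pair_expression_divergence([("a", "zz")], m)
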