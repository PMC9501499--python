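import itertools

import numpy as np
import pytest
import skbio

from qmprofiler.diversity import (
    bray_curtis,
    bray_curtis_matrix,
    observed,
    pcoa,
    permanova,
    rarefy,
    shannon,
    simpson,
)


class TestRarefy:
    def test_identity_at_full_depth(self, rng):
        counts = np.array([5, 0, 7])
        np.testing.assert_array_equal(rarefy(counts, 12, rng), counts)

    def test_single_taxon(self, rng):
        np.testing.assert_array_equal(rarefy(np.array([500]), 100, rng), [100])

    def test_depth_above_library_size_directs_to_filter(self, rng):
        with pytest.raises(ValueError, match="filter"):
            rarefy(np.array([10, 10]), 100, rng)

    def test_totals_and_bounds(self, rng):
        counts = np.array([40, 0, 25, 35])
        for _ in range(20):
            r = rarefy(counts, 30, rng)
            assert r.sum() == 30 and (r <= counts).all() and (r >= 0).all()

    def test_expected_counts_proportional(self, rng):
        # E[rarefied_j] = depth * p_j (without replacement): check 1000 draws
        counts = np.array([600, 300, 100])
        depth = 200
        draws = np.array([rarefy(counts, depth, rng) for _ in range(1000)])
        p = counts / counts.sum()
        expect = depth * p
        # hypergeometric variance with finite-population correction
        n_tot = counts.sum()
        var = depth * p * (1 - p) * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / 1000)
        assert (np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9).all()


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        counts = np.array([5, 5, 5, 5])
        assert shannon(counts) == pytest.approx(np.log(4), rel=1e-12)
        assert simpson(counts) == pytest.approx(0.75, rel=1e-12)
        assert observed(counts) == 4

    def test_single_taxon(self):
        counts = np.array([10, 0])
        assert shannon(counts) == 0.0
        assert simpson(counts) == pytest.approx(0.0, abs=1e-12)
        assert observed(counts) == 1

    def test_hand_computed_mixed_counts(self):
        counts = np.array([1, 1, 2])
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert shannon(counts) == pytest.approx(expected, rel=1e-12)
        assert shannon(counts) == pytest.approx(1.0397, abs=1e-4)

    def test_order_and_scaling_invariance(self):
        counts = np.array([3, 9, 1, 7])
        for f in (shannon, simpson):
            assert f(counts) == pytest.approx(f(counts[::-1]), rel=1e-12)
            assert f(counts) == pytest.approx(f(counts * 13), rel=1e-12)

    def test_empty_sample_rejected(self):
        for f in (shannon, simpson, observed):
            with pytest.raises(ValueError, match="empty"):
                f(np.zeros(3))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bray_curtis(x, x) == 0.0
        assert bray_curtis(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 1.0

    def test_hand_computed(self):
        assert bray_curtis(np.array([1.0, 2.0]), np.array([3.0, 0.0])) == pytest.approx(2 / 3)

    def test_matrix_matches_pairwise(self, rng):
        x = rng.dirichlet(np.ones(5), size=4)
        d = bray_curtis_matrix(x)
        assert d.shape == (4, 4)
        for i, j in itertools.combinations(range(4), 2):
            assert d[i, j] == pytest.approx(bray_curtis(x[i], x[j]), rel=1e-12)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(2), np.zeros(2))


class TestPcoa:
    def test_equilateral_eigenvalues_equal(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)

    def test_collinear_points_recover_gaps(self):
        # points at 0, 1, 4 on a line
        pos = np.array([0.0, 1.0, 4.0])
        d = np.abs(pos[:, None] - pos[None, :])
        res = pcoa(d)
        assert res.eigenvalues[0] > 0
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
        axis = res.coordinates[:, 0]
        gaps = np.abs(np.diff(np.sort(axis)))
        np.testing.assert_allclose(sorted(gaps), [1.0, 3.0], atol=1e-9)

    def test_duplicate_samples_coincide(self):
        d = np.array(
            [[0, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float
        )
        res = pcoa(d)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


def _brute_force_permanova_p(d, labels):
    """Independent oracle: exhaustive permutation of the classic group-SS
    pseudo-F computed directly from within-group squared dissimilarities."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels))

    def pseudo_f(lab):
        ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = d[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))

    f_obs = pseudo_f(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        f = pseudo_f(labels[list(perm)])
        count += f >= f_obs - 1e-12
        total += 1
    return count / total, f_obs


class TestPermanova:
    def make_distance(self, rng, n=10, p=20):
        return bray_curtis_matrix(rng.dirichlet(np.ones(p), size=n))

    def test_maximal_separation(self):
        # two internally identical groups far apart: minimal p, R^2 near 1.
        # Groups of 10 make label permutations that reproduce the partition
        # (which would tie the observed F) vanishingly rare.
        x = np.vstack([np.tile([1.0, 0.0], (10, 1)), np.tile([0.0, 1.0], (10, 1))])
        d = bray_curtis_matrix(x)
        res = permanova(d, ["a"] * 10 + ["b"] * 10, 999, np.random.default_rng(0))
        assert res.p_value["group"] == pytest.approx(1 / 1000)
        assert res.r_squared["group"] > 0.99

    def test_single_group_rejected(self, rng):
        d = self.make_distance(rng, n=6)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(d, ["a"] * 6, 999, rng)

    def test_matches_skbio_statistic(self, rng):
        d = self.make_distance(rng)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(d, labels, 999, np.random.default_rng(1))
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d), labels, permutations=999
        )
        assert res.pseudo_f["group"] == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_exhaustive_oracle_agreement(self, rng):
        # 6 samples: exact p by enumerating all 720 label permutations vs
        # Monte-Carlo at 10^4 draws
        d = self.make_distance(rng, n=6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        p_exact, _ = _brute_force_permanova_p(d, labels)
        res = permanova(d, list(labels), 9999, np.random.default_rng(2))
        assert abs(res.p_value["group"] - p_exact) < 0.02

    def test_two_factor_sequential_r2_sums_below_one(self, rng):
        d = self.make_distance(rng, n=12)
        res = permanova(
            d,
            {"diet": ["CD", "FFD"] * 6, "compartment": ["si"] * 4 + ["ce"] * 4 + ["co"] * 4},
            n_permutations=99,
            rng=rng,
        )
        assert set(res.r_squared) == {"diet", "compartment"}
        assert 0 <= sum(res.r_squared.values()) <= 1
        for p in res.p_value.values():
            assert 1 / 100 <= p <= 1
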