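import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from qmprofiler.data_model import Diet
from qmprofiler.diff_guilds import (
    ArtifactFlag,
    build_l2fc_report,
    diet_test,
    guild_cluster,
    kendall_concordance,
    l2fc,
    report_to_frame,
    select_top_taxa,
)
from qmprofiler.qmp_core import profile_study
from qmprofiler.synthetic_data import generate_study

from .conftest import make_config


class TestSelectTopTaxa:
    def test_ranked_by_mean_with_lexicographic_ties(self):
        df = pd.DataFrame({"b": [1, 3], "a": [3, 1], "c": [5, 5]})
        assert select_top_taxa(df, 2) == ["c", "a"]
        assert select_top_taxa(df, 3) == ["c", "a", "b"]

    def test_fewer_taxa_than_k_returns_all(self, caplog):
        df = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [0.5]})
        assert len(select_top_taxa(df, 50)) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_top_taxa(pd.DataFrame())


class TestL2fc:
    def test_equal_means_zero(self):
        assert l2fc(np.array([1.0, 3.0]), np.array([2.0, 2.0]), 0.5) == 0.0

    def test_double_zero_is_zero_for_any_pseudocount(self):
        for pc in (1e-6, 1.0, 100.0):
            assert l2fc(np.zeros(3), np.zeros(2), pc) == 0.0

    def test_hand_computed(self):
        assert l2fc(np.array([3.0]), np.array([1.0]), 1.0) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            l2fc(np.array([-1.0]), np.array([1.0]), 1.0)
        with pytest.raises(ValueError, match="pseudocount"):
            l2fc(np.array([1.0]), np.array([1.0]), 0.0)


class TestDietTest:
    def test_identical_groups_p_one(self):
        assert diet_test(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0])) == 1.0

    def test_huge_shift_tiny_p(self):
        p = diet_test(np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0]),
                      equal_var=True)
        assert p < 1e-6

    def test_small_groups_nan(self):
        assert np.isnan(diet_test(np.array([1.0]), np.array([1.0, 2.0])))


def _profiled(cfg, seed):
    study = generate_study(cfg, seed=seed)
    return study, profile_study(study.read_table, study.records, study.copy_numbers)


class TestL2fcReport:
    def test_planted_degrader_flagged_as_relative_only_increase(self):
        cfg = make_config(n_taxa=20, n_mice=10, n_degraders=2)
        study, abs_table = _profiled(cfg, 11)
        rep = report_to_frame(build_l2fc_report(abs_table, study.records, top_k=20))
        deg = rep[rep.taxon_id.isin(["t18", "t19"])]
        assert (deg.artifact_flag == ArtifactFlag.RELATIVE_ONLY_INCREASE.value).any()

    def test_artifact_flag_invariant(self):
        cfg = make_config(n_taxa=20, n_mice=6, n_degraders=2)
        study, abs_table = _profiled(cfg, 3)
        rep = build_l2fc_report(abs_table, study.records, top_k=20)
        for r in rep:
            expected_flag = r.artifact_flag == ArtifactFlag.RELATIVE_ONLY_INCREASE
            condition = (
                r.significant_relative and r.l2fc_relative > 0
                and not r.significant_absolute
            )
            assert expected_flag == condition

    def test_diet_label_swap_negates_l2fc(self):
        cfg = make_config(n_taxa=8, n_mice=4)
        study, abs_table = _profiled(cfg, 7)
        rep = report_to_frame(build_l2fc_report(abs_table, study.records, top_k=8))
        swapped_records = []
        for r in study.records:
            import dataclasses
            swapped_records.append(dataclasses.replace(
                r, diet=Diet.CD if r.diet == Diet.FFD else Diet.FFD
            ))
        rep_swapped = report_to_frame(
            build_l2fc_report(abs_table, swapped_records, top_k=8)
        )
        merged = rep.merge(rep_swapped, on=["taxon_id", "compartment"])
        np.testing.assert_allclose(
            merged.l2fc_absolute_x, -merged.l2fc_absolute_y, rtol=1e-9
        )
        np.testing.assert_allclose(
            merged.l2fc_relative_x, -merged.l2fc_relative_y, rtol=1e-9
        )

    def test_single_diet_compartment_skipped(self):
        cfg = make_config(n_taxa=8, n_mice=4)
        study, abs_table = _profiled(cfg, 7)
        cd_only = [r for r in study.records if r.diet == Diet.CD]
        cd_ids = [r.sample_id for r in cd_only]
        sub = abs_table.frame("abs_per_compartment").loc[cd_ids]
        import dataclasses

        abs_cd = dataclasses.replace(
            abs_table,
            sample_ids=cd_ids,
            taxon_ids=abs_table.taxon_ids,
            rel_corrected=abs_table.frame("rel_corrected").loc[cd_ids].to_numpy(),
            abs_per_g=abs_table.frame("abs_per_g").loc[cd_ids].to_numpy(),
            abs_per_compartment=sub.to_numpy(),
        )
        assert build_l2fc_report(abs_cd, cd_only, top_k=8) == []


class TestKendallW:
    def test_perfect_concordance(self):
        a = np.vstack([[1, 2, 3, 4]] * 3)
        w, p = kendall_concordance(a)
        assert w == pytest.approx(1.0)
        assert p < 0.2  # chi2 approximation, small n

    def test_reversed_rankings_give_zero(self):
        a = np.array([[1, 2, 3, 4], [4, 3, 2, 1]])
        w, _ = kendall_concordance(a)
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_rank_sum_formula(self):
        a = np.array([[3, 1, 4, 2], [7, 2, 9, 9], [5, 5, 8, 1]], dtype=float)
        w, _ = kendall_concordance(a)
        # independent oracle: direct formula with explicit tie correction
        m, n = a.shape
        ranks = np.vstack([stats.rankdata(row) for row in a])
        R = ranks.sum(axis=0)
        s = ((R - m * (n + 1) / 2) ** 2).sum()
        T = sum(
            (c ** 3 - c).sum()
            for row in a
            for c in [np.unique(row, return_counts=True)[1]]
        )
        w_direct = 12 * s / (m ** 2 * (n ** 3 - n) - m * T)
        assert w == pytest.approx(w_direct, rel=1e-12)

    def test_no_tie_relation_to_mean_spearman(self, rng):
        # without ties, W = ((m-1) * mean pairwise rho + 1) / m
        a = rng.permuted(np.tile(np.arange(1.0, 9.0), (4, 1)), axis=1)
        w, _ = kendall_concordance(a)
        rhos = [
            stats.spearmanr(a[i], a[j]).statistic
            for i in range(4) for j in range(i + 1, 4)
        ]
        assert w == pytest.approx((3 * np.mean(rhos) + 1) / 4, rel=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            kendall_concordance(np.ones((3, 4)))


class TestGuildCluster:
    def planted_blocks(self, rng, n_samples=24, n_a=10, n_b=6):
        base_a = rng.normal(size=n_samples)
        base_b = rng.normal(size=n_samples)
        cols = {}
        for i in range(n_a):
            cols[f"a{i:02d}"] = base_a + rng.normal(scale=0.3, size=n_samples)
        for i in range(n_b):
            cols[f"b{i:02d}"] = base_b + rng.normal(scale=0.3, size=n_samples)
        return pd.DataFrame(cols)

    def test_planted_two_blocks_recovered(self, rng):
        df = self.planted_blocks(rng)
        res = guild_cluster(df, k_range=range(2, 6))
        assert res.k_selected == 2
        truth = [0] * 10 + [1] * 6
        found = [res.assignments[t] for t in df.columns]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_monotone_transform_invariance(self, rng):
        df = np.abs(self.planted_blocks(rng)) + 0.1
        res1 = guild_cluster(df, k_range=range(2, 5))
        res2 = guild_cluster(df ** 3, k_range=range(2, 5))  # rank-preserving
        assert res1.k_selected == res2.k_selected
        a1 = [res1.assignments[t] for t in df.columns]
        a2 = [res2.assignments[t] for t in df.columns]
        assert adjusted_rand_score(a1, a2) == 1.0

    def test_silhouette_selection_matches_brute_force(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        from sklearn.metrics import silhouette_score

        df = self.planted_blocks(rng)
        res = guild_cluster(df, k_range=range(2, 7))
        rho = stats.spearmanr(df.to_numpy(), axis=0).statistic
        dist = 1 - rho
        np.fill_diagonal(dist, 0)
        z = linkage(squareform(dist, checks=False), method="ward")
        brute = {
            k: silhouette_score(dist, fcluster(z, k, criterion="maxclust"),
                                metric="precomputed")
            for k in range(2, 7)
        }
        assert res.k_selected == max(brute, key=brute.get)
        for k, s in brute.items():
            assert res.silhouette_by_k[k] == pytest.approx(s, rel=1e-9)

    def test_constant_taxon_dropped_with_warning(self, rng, caplog):
        df = self.planted_blocks(rng)
        df["flat"] = 1.0
        res = guild_cluster(df, k_range=range(2, 4))
        assert res.dropped_taxa == ["flat"]
        assert "flat" not in res.assignments
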