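import numpy as np
import pandas as pd
import pytest

from qmprofiler.data_model import validate_replicates
from qmprofiler.qmp_core import copy_number_correct
from qmprofiler.synthetic_data import (
    ScenarioConfig,
    ScenarioError,
    effective_ffd_multipliers,
    generate_study,
    load_scenario,
    sample_reads,
    write_synthetic_study,
)

from .conftest import make_config


class TestSampleReads:
    def test_expected_fractions_weighted_by_copy_number(self, rng):
        reads = sample_reads(np.array([1.0, 1.0]), np.array([1.0, 2.0]), 300_000, rng)
        # p_j = l_j c_j / sum l_k c_k = [1/3, 2/3]
        assert reads.sum() == 300_000
        assert reads[1] / reads.sum() == pytest.approx(2 / 3, abs=0.005)

    def test_zero_depth_gives_zero_vector(self, rng):
        np.testing.assert_array_equal(
            sample_reads(np.array([1.0, 2.0]), np.ones(2), 0, rng), [0, 0]
        )

    def test_single_taxon_gets_all_reads(self, rng):
        np.testing.assert_array_equal(
            sample_reads(np.array([5.0]), np.array([3.0]), 123, rng), [123]
        )

    def test_all_zero_loads_rejected(self, rng):
        with pytest.raises(ValueError, match="all-zero"):
            sample_reads(np.zeros(3), np.ones(3), 10, rng)


class TestGenerateStudy:
    def test_deterministic_given_seed(self):
        cfg = make_config()
        a = generate_study(cfg, seed=5)
        b = generate_study(cfg, seed=5)
        np.testing.assert_array_equal(a.read_table.counts, b.read_table.counts)
        pd.testing.assert_frame_equal(
            a.ground_truth.true_load_per_g, b.ground_truth.true_load_per_g
        )
        assert [r.cell_density_cells_per_g for r in a.records] == [
            r.cell_density_cells_per_g for r in b.records
        ]
        c = generate_study(cfg, seed=6)
        assert (a.read_table.counts != c.read_table.counts).any()

    def test_infinite_depth_limit_recovers_weighted_fractions(self):
        # noise-free, depth 1e6, 2 taxa: observed read fractions converge to
        # the copy-number-weighted ground-truth proportions
        cfg = make_config(n_taxa=2, noise=False, depth=1_000_000, n_degraders=0)
        study = generate_study(cfg, seed=3)
        truth = study.ground_truth.true_load_per_g
        cvec = np.array([t.copy_number for t in cfg.taxa])
        for i, sid in enumerate(study.read_table.sample_ids):
            counts = study.read_table.counts[i]
            expected = truth.loc[sid].to_numpy() * cvec
            expected /= expected.sum()
            observed = counts / counts.sum()
            np.testing.assert_allclose(observed, expected, atol=0.005)

    def test_closed_form_ground_truth_l2fc(self):
        cfg = make_config(n_taxa=6, diet_load_ratio=0.2, n_degraders=1)
        gt = generate_study(cfg, seed=0).ground_truth.l2fc
        deg = gt.query("taxon_id == 't05'").iloc[0]
        assert deg.l2fc_absolute == pytest.approx(0.0, abs=1e-12)
        assert deg.l2fc_relative == pytest.approx(-np.log2(0.2), abs=1e-12)

    def test_total_load_ratio_is_exact(self):
        cfg = make_config(diet_load_ratio=0.2)
        m_eff = effective_ffd_multipliers(cfg, "cecum")
        f = np.array([t.fraction_in("cecum") for t in cfg.taxa])
        assert float((f * m_eff).sum()) == pytest.approx(0.2, rel=1e-12)

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ScenarioError):
            make_config(n_taxa=0)
        with pytest.raises(ScenarioError):
            make_config(n_mice=1)
        with pytest.raises(ScenarioError):
            make_config(diet_load_ratio=0.0)

    def test_fraction_sum_validated(self):
        from qmprofiler.synthetic_data import CompartmentSpec, TaxonSpec

        taxa = [TaxonSpec("a", "neutral", 0.6), TaxonSpec("b", "neutral", 0.6)]
        comps = [CompartmentSpec(
            "cecum", 1e10, {"CD": 0.3, "FFD": 0.3}, 0.1, {"CD": 0.2, "FFD": 0.2}
        )]
        with pytest.raises(ScenarioError, match="sum"):
            ScenarioConfig(name="x", n_mice_per_diet=2, taxa=taxa, compartments=comps)

    def test_replicate_means_match_records(self):
        study = generate_study(make_config(), seed=9)
        validate_replicates(study.records, study.cell_count_replicates)

    def test_inverse_consistency_closed_form(self):
        # correcting the *expected* read fractions (load x copy number,
        # normalised) recovers the true load proportions exactly
        cfg = make_config(noise=False)
        study = generate_study(cfg, seed=2)
        cvec = np.array([t.copy_number for t in cfg.taxa])
        truth = study.ground_truth.true_load_per_g.iloc[0].to_numpy()
        expected_fracs = truth * cvec / (truth * cvec).sum()
        recovered = copy_number_correct(expected_fracs, cvec)
        np.testing.assert_allclose(recovered, truth / truth.sum(), rtol=1e-12)

    def test_feces_samples_have_no_weights(self):
        study = generate_study(make_config(with_feces=True), seed=1)
        fecal = [r for r in study.records if r.compartment.value == "feces"]
        assert fecal and all(r.content_wet_weight_g is None for r in fecal)
        assert {r.day for r in fecal} == {0, 2, 7}


def test_packaged_cecum_collapse_scenario_structure():
    cfg = load_scenario("cecum_collapse")
    assert len(cfg.taxa) == 50
    guilds = pd.Series([t.guild for t in cfg.taxa]).value_counts()
    assert guilds["fiber_responsive"] == 31
    assert guilds["mucus_degrader"] >= 1
    assert cfg.diet_load_ratio == 0.2
    akk = next(t for t in cfg.taxa if t.taxon_id == "Akkermansia")
    assert akk.guild == "mucus_degrader" and akk.ffd_absolute_multiplier == 1.0


def test_write_synthetic_study_round_trip(tmp_path):
    from qmprofiler.data_model import read_study

    study = generate_study(make_config(with_tracer=True), seed=4)
    paths = write_synthetic_study(study, tmp_path)
    table, records, copynums = read_study(
        paths["counts"], paths["metadata"], paths["copy_numbers"]
    )
    np.testing.assert_array_equal(table.counts, study.read_table.counts)
    assert len(records) == len(study.records)
    assert paths["ground_truth"].exists() and paths["tracer"].exists()
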