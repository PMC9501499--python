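import numpy as np
import pytest

from qmprofiler.synthetic_data import (
    CompartmentSpec,
    ScenarioConfig,
    TaxonSpec,
    TracerScenario,
)


def make_config(
    n_taxa: int = 6,
    n_mice: int = 4,
    diet_load_ratio: float = 0.2,
    depth: int = 50_000,
    noise: bool = True,
    n_degraders: int = 1,
    compartment_names: tuple[str, ...] = ("cecum",),
    with_feces: bool = False,
    with_tracer: bool = False,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """Small scenario builder for tests; noise=False zeroes every noise source."""
    fracs = np.arange(n_taxa, 0, -1, dtype=float)
    fracs /= fracs.sum()
    taxa = []
    for i in range(n_taxa):
        # degraders take the rarest ranks so their pinned load stays below
        # the FFD total-load ratio
        guild = "mucus_degrader" if i >= n_taxa - n_degraders else "fiber_responsive"
        taxa.append(TaxonSpec(
            taxon_id=f"t{i:02d}",
            guild=guild,
            baseline_fraction=float(fracs[i]),
            ffd_absolute_multiplier=1.0 if guild == "mucus_degrader" else 0.15,
            copy_number=float(1 + i % 4),
        ))
    comps = [
        CompartmentSpec(
            name=name,
            baseline_load_cells_per_g=2e10,
            wet_weight_mean_g={"CD": 0.35, "FFD": 0.35},
            wet_weight_cv=0.15 if noise else 0.0,
            dry_fraction={"CD": 0.2, "FFD": 0.2},
        )
        for name in compartment_names
    ]
    if with_feces:
        comps.append(CompartmentSpec(name="feces", baseline_load_cells_per_g=1e11))
    tracer = None
    if with_tracer:
        per = lambda cd, ffd: {  # noqa: E731
            "CD": {n: cd for n in compartment_names},
            "FFD": {n: ffd for n in compartment_names},
        }
        tracer = TracerScenario(
            control_atom_pct_13C=1.07,
            measurement_cv=0.05 if noise else 0.0,
            labeled_excess_atom_pct=per(0.4, 0.2),
            pct_C=per(44.0, 38.0),
            pct_N=per(5.5, 5.7),
        )
    kwargs = dict(
        name="test",
        seed=seed,
        n_mice_per_diet=n_mice,
        taxa=taxa,
        compartments=comps,
        diet_load_ratio=diet_load_ratio,
        seq_depth_mean=depth,
        seq_depth_dispersion=20.0 if noise else None,
        cellcount_cv=0.15 if noise else 0.0,
        mouse_effect_sigma=0.3 if noise else 0.0,
        block_factor_sigma=0.4 if noise else 0.0,
        taxon_noise_sigma=0.2 if noise else 0.0,
        feces_days=(0, 2, 7) if with_feces else (),
        tracer=tracer,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_study_dir(tmp_path):
    """3-sample, 2-taxon study TSVs on disk."""
    (tmp_path / "counts.tsv").write_text(
        "taxon_id\ts1\ts2\ts3\n"
        "Akkermansia\t10\t0\t25\n"
        "Muribaculum\t90\t40\t75\n"
    )
    (tmp_path / "metadata.tsv").write_text(
        "sample_id\tmouse_id\tsex\tdiet\tday\tcompartment\tcontent_wet_weight_g\t"
        "content_dry_weight_g\ttissue_weight_g\tbody_weight_g\tcell_density_cells_per_g\n"
        "s1\tm1\tF\tCD\t7\tcecum\t0.5\t0.1\t0.4\t22\t2e10\n"
        "s2\tm2\tM\tFFD\t7\tcecum\t0.3\t0.05\t0.35\t21\t5e9\n"
        "s3\tm3\tF\tCD\t7\tcolon\t0.2\t0.05\t0.2\t23\t1e10\n"
    )
    (tmp_path / "copy_numbers.tsv").write_text(
        "taxon_id\tcopy_number\nAkkermansia\t3\nMuribaculum\t2\n"
    )
    return tmp_path
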