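"""Synthetic quantitative-microbiome-profiling studies with known ground truth.

The generator emulates a two-diet mouse experiment: mice on a standard
chow control diet (CD) or a fiber-free diet (FFD), stool sampled on days
0/2/7, and terminal luminal contents from small intestine, cecum, and
colon at day 7. Each scenario plants

* diet-dependent absolute taxon loads — under FFD the total load of each
  compartment drops to ``diet_load_ratio`` times the CD total while
  mucus-degrader taxa keep their absolute load fixed, reproducing the
  compositional trap in which an unchanged taxon appears to bloom in
  relative abundance;
* copy-number-biased multinomial read sampling — a taxon with c 16S
  operons per genome contributes reads in proportion to load x c, the
  inverse of the correction the profiling stage applies;
* noisy flow-cytometry cell densities (lognormal triplicates), a
  per-mouse lognormal random effect, and a lognormal latent factor per
  co-abundance block (declining bulk vs. constant mucus degraders) that
  gives guild clustering a recoverable 2-block structure;
* a stable-isotope tracer layer: 13C enrichment of luminal biomass with
  unlabeled-control animals, diet/compartment-specific %C and %N.

Every observable is traceable to the stored ground truth, so downstream
stages can be tested for exact inverse consistency (no noise) and for
statistical recovery (with noise).

The default scenario ships as ``scenarios/cecum_collapse.yaml``: 50
genera, 31 fiber-responsive taxa collapsing under FFD, constant-load
mucus degraders (*Akkermansia* and companions), total load falling to
20% of CD.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    FLOAT_FORMAT,
    CellCountReplicates,
    Compartment,
    CopyNumberTable,
    Diet,
    SampleRecord,
    TaxonReadTable,
)
from .tracer_physiology import CtRecord, TracerMeasurement

__all__ = [
    "TaxonSpec",
    "CompartmentSpec",
    "TracerScenario",
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_study",
    "sample_reads",
    "simulate_ct_records",
    "load_scenario",
    "write_synthetic_study",
]

NATURAL_ABUNDANCE_15N_ATOM_PCT = 0.366

GUILDS = ("fiber_responsive", "mucus_degrader", "neutral")


class ScenarioError(ValueError):
    """The scenario configuration is degenerate or inconsistent."""


@dataclass
class TaxonSpec:
    """One genus in a scenario.

    ``baseline_fraction`` is the taxon's share of the CD total load,
    either a scalar (same in every compartment) or a mapping keyed by
    compartment name. ``ffd_absolute_multiplier`` scales the taxon's
    absolute per-gram load under FFD; mucus degraders default to 1.0
    (constant load) and are held fixed when the generator renormalises
    the remaining taxa to hit ``diet_load_ratio`` exactly.
    """

    taxon_id: str
    guild: str
    baseline_fraction: float | Mapping[str, float]
    ffd_absolute_multiplier: float | None = None
    copy_number: float = 1.0

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ScenarioError(f"{self.taxon_id}: unknown guild {self.guild!r}")
        if self.ffd_absolute_multiplier is None:
            self.ffd_absolute_multiplier = 1.0 if self.guild == "mucus_degrader" else 0.5
        if self.ffd_absolute_multiplier < 0:
            raise ScenarioError(f"{self.taxon_id}: negative FFD multiplier")
        if self.copy_number < 1:
            raise ScenarioError(f"{self.taxon_id}: copy number must be >= 1")

    def fraction_in(self, compartment: str) -> float:
        if isinstance(self.baseline_fraction, Mapping):
            return float(self.baseline_fraction[compartment])
        return float(self.baseline_fraction)


@dataclass
class CompartmentSpec:
    """Baseline microbial load and content-weight distributions.

    Weight means/dry fractions are per diet (``{"CD": ..., "FFD": ...}``);
    feces carries no content weight and uses ``wet_weight_mean_g=None``.
    """

    name: str
    baseline_load_cells_per_g: float
    wet_weight_mean_g: Mapping[str, float] | None = None
    wet_weight_cv: float = 0.15
    dry_fraction: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        Compartment(self.name)  # validate against the closed enum
        if self.baseline_load_cells_per_g <= 0:
            raise ScenarioError(f"{self.name}: baseline load must be > 0")
        if self.name != Compartment.FECES.value and self.wet_weight_mean_g is None:
            raise ScenarioError(f"{self.name}: intestinal compartments need weights")


@dataclass
class TracerScenario:
    """Isotope and elemental parameters by diet and compartment."""

    control_atom_pct_13C: float = 1.07
    labeled_excess_atom_pct: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    pct_C: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    pct_N: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    measurement_cv: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.control_atom_pct_13C <= 100:
            raise ScenarioError("control atom% 13C out of [0, 100]")
        if self.measurement_cv < 0:
            raise ScenarioError("measurement_cv must be >= 0")
        for diet in self.pct_C:
            for comp in self.pct_C[diet]:
                c, n = self.pct_C[diet][comp], self.pct_N.get(diet, {}).get(comp, 0.0)
                if c + n > 100:
                    raise ScenarioError(f"{diet}/{comp}: %C + %N exceeds 100")


@dataclass
class ScenarioConfig:
    name: str
    n_mice_per_diet: int
    taxa: list[TaxonSpec]
    compartments: list[CompartmentSpec]
    diet_load_ratio: float = 0.2
    seq_depth_mean: int = 50_000
    seq_depth_dispersion: float | None = 20.0  # NB size parameter; None = fixed depth
    cellcount_cv: float = 0.15
    mouse_effect_sigma: float = 0.3
    block_factor_sigma: float = 0.4
    taxon_noise_sigma: float = 0.2
    feces_days: tuple[int, ...] = (0, 2, 7)
    n_tracer_controls_per_diet: int = 2
    tracer: TracerScenario | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_diet < 2:
            raise ScenarioError("need at least 2 mice per diet")
        if not self.taxa:
            raise ScenarioError("scenario must define at least one taxon")
        if not self.compartments:
            raise ScenarioError("scenario must define at least one compartment")
        if not 0 < self.diet_load_ratio <= 1:
            raise ScenarioError("diet_load_ratio must lie in (0, 1]")
        if self.cellcount_cv < 0:
            raise ScenarioError("cellcount_cv must be >= 0")
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ScenarioError("duplicate taxon_id in scenario")
        for comp in self.compartments:
            total = sum(t.fraction_in(comp.name) for t in self.taxa)
            if abs(total - 1.0) > 1e-9:
                raise ScenarioError(
                    f"{comp.name}: baseline fractions sum to {total!r}, expected 1"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def intestinal_compartments(self) -> list[CompartmentSpec]:
        return [c for c in self.compartments if c.name != Compartment.FECES.value]

    def copy_number_table(self) -> CopyNumberTable:
        return CopyNumberTable({t.taxon_id: t.copy_number for t in self.taxa})

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["taxa"] = [TaxonSpec(**t) for t in d["taxa"]]
        d["compartments"] = [CompartmentSpec(**c) for c in d["compartments"]]
        if d.get("tracer") is not None:
            d["tracer"] = TracerScenario(**d["tracer"])
        if "feces_days" in d:
            d["feces_days"] = tuple(d["feces_days"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_scenario(name_or_path: str | Path) -> ScenarioConfig:
    """Load a scenario YAML; bare names resolve to packaged scenarios."""
    p = Path(name_or_path)
    if p.exists():
        return ScenarioConfig.from_yaml(p)
    res = importlib.resources.files("qmprofiler") / "scenarios" / f"{Path(name_or_path).stem}.yaml"
    if not res.is_file():
        raise FileNotFoundError(f"no scenario file or packaged scenario named {name_or_path!r}")
    return ScenarioConfig.from_dict(yaml.safe_load(res.read_text()))


# ---------------------------------------------------------------------------
# Scenario algebra (closed-form ground truth)
# ---------------------------------------------------------------------------

def effective_ffd_multipliers(config: ScenarioConfig, compartment: str) -> np.ndarray:
    """Per-taxon FFD load multipliers after total-load renormalisation.

    Mucus-degrader multipliers are honoured exactly; the remaining taxa
    are rescaled by a common factor so the FFD total equals
    ``diet_load_ratio`` x the CD total. Hence a degrader with multiplier
    1.0 has absolute log2 fold change exactly 0 and relative log2 fold
    change exactly ``-log2(diet_load_ratio)``.
    """
    f = np.array([t.fraction_in(compartment) for t in config.taxa])
    m = np.array([t.ffd_absolute_multiplier for t in config.taxa], dtype=float)
    pinned = np.array([t.guild == "mucus_degrader" for t in config.taxa])
    s_pin = float((f[pinned] * m[pinned]).sum())
    s_free = float((f[~pinned] * m[~pinned]).sum())
    if not pinned.all():
        if s_free <= 0:
            raise ScenarioError("free taxa carry zero load; cannot renormalise")
        gamma = (config.diet_load_ratio - s_pin) / s_free
        if gamma <= 0:
            raise ScenarioError(
                f"{compartment}: pinned taxa alone exceed diet_load_ratio "
                f"({s_pin:.3g} > {config.diet_load_ratio:.3g})"
            )
        m = m.copy()
        m[~pinned] *= gamma
    return m


def true_l2fc_table(config: ScenarioConfig) -> pd.DataFrame:
    """Closed-form per-taxon absolute and relative log2 fold changes (FFD/CD)."""
    rows = []
    for comp in config.intestinal_compartments:
        m_eff = effective_ffd_multipliers(config, comp.name)
        with np.errstate(divide="ignore"):
            l2fc_abs = np.log2(m_eff)
            l2fc_rel = np.log2(m_eff / config.diet_load_ratio)
        for t, a, r in zip(config.taxa, l2fc_abs, l2fc_rel):
            rows.append({
                "taxon_id": t.taxon_id,
                "compartment": comp.name,
                "guild": t.guild,
                "l2fc_absolute": a,
                "l2fc_relative": r,
            })
    return pd.DataFrame(rows)


def true_flux_table(config: ScenarioConfig) -> pd.DataFrame:
    """Expected secreted-carbon flux per diet and compartment (mg 13C excess)."""
    if config.tracer is None:
        return pd.DataFrame(columns=["diet", "compartment", "flux_mg_13C_excess"])
    rows = []
    for diet in ("CD", "FFD"):
        for comp in config.intestinal_compartments:
            excess = config.tracer.labeled_excess_atom_pct[diet][comp.name]
            pct_c = config.tracer.pct_C[diet][comp.name]
            dry_mg = comp.wet_weight_mean_g[diet] * comp.dry_fraction[diet] * 1000.0
            rows.append({
                "diet": diet,
                "compartment": comp.name,
                "flux_mg_13C_excess": (excess / 100.0) * (pct_c / 100.0) * dry_mg,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent state behind a synthetic study."""

    true_load_per_g: pd.DataFrame            # samples x taxa, cells/g
    true_load_per_compartment: pd.DataFrame  # samples x taxa, NaN for feces
    true_total_density: pd.Series            # cells/g per sample
    guilds: dict[str, str]                   # taxon -> guild
    block_labels: dict[str, str]             # taxon -> planted correlation block
    l2fc: pd.DataFrame                       # closed-form fold changes
    flux: pd.DataFrame                       # expected tracer flux


@dataclass
class SyntheticStudy:
    config: ScenarioConfig
    read_table: TaxonReadTable
    records: list[SampleRecord]
    copy_numbers: CopyNumberTable
    cell_count_replicates: dict[str, CellCountReplicates]
    tracer_measurements: list[TracerMeasurement]
    ground_truth: GroundTruth


def sample_reads(
    true_loads: np.ndarray,
    copy_numbers: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial read sampling biased by 16S copy number.

    Read probabilities are proportional to load x copy number: the
    forward model whose inverse is the profiling stage's copy-number
    correction.
    """
    loads = np.asarray(true_loads, dtype=float)
    c = np.asarray(copy_numbers, dtype=float)
    if np.any(loads < 0):
        raise ValueError("negative true load")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    weights = loads * c
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot sample reads from all-zero loads")
    if depth == 0:
        return np.zeros(loads.shape, dtype=np.int64)
    return rng.multinomial(depth, weights / total)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-1 lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _lognormal_sigma_factor(rng: np.random.Generator, sigma: float, size=None):
    """Mean-1 lognormal multiplier parameterised by log-scale sigma."""
    if sigma <= 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_study(config: ScenarioConfig, seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study; deterministic given the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    taxa = config.taxa
    taxon_ids = config.taxon_ids
    n_taxa = len(taxa)
    cvec = np.array([t.copy_number for t in taxa], dtype=float)
    blocks = {
        t.taxon_id: ("constant" if t.guild == "mucus_degrader" else "responsive")
        for t in taxa
    }
    block_names = sorted(set(blocks.values()))
    block_of = np.array([block_names.index(blocks[t]) for t in taxon_ids])

    mice = []
    for diet in (Diet.CD, Diet.FFD):
        for i in range(config.n_mice_per_diet):
            mice.append({
                "mouse_id": f"{diet.value}m{i + 1:02d}",
                "diet": diet,
                "sex": "F" if i % 2 else "M",
                "is_tracer_control": i < config.n_tracer_controls_per_diet,
            })
    mouse_mult = {
        m["mouse_id"]: float(_lognormal_sigma_factor(rng, config.mouse_effect_sigma))
        for m in mice
    }
    body_weight = {m["mouse_id"]: float(rng.normal(22.0, 1.5)) for m in mice}

    m_eff = {
        comp.name: effective_ffd_multipliers(config, comp.name)
        for comp in config.compartments
    }

    sample_plan: list[tuple[dict, CompartmentSpec, int]] = []
    feces_spec = next(
        (c for c in config.compartments if c.name == Compartment.FECES.value), None
    )
    for m in mice:
        if feces_spec is not None:
            for day in config.feces_days:
                sample_plan.append((m, feces_spec, day))
        for comp in config.intestinal_compartments:
            sample_plan.append((m, comp, 7))

    records: list[SampleRecord] = []
    replicates: dict[str, CellCountReplicates] = {}
    tracer_measurements: list[TracerMeasurement] = []
    counts = np.zeros((len(sample_plan), n_taxa), dtype=np.int64)
    true_per_g = np.zeros((len(sample_plan), n_taxa))
    true_per_comp = np.full((len(sample_plan), n_taxa), np.nan)
    sample_ids: list[str] = []

    for i, (m, comp, day) in enumerate(sample_plan):
        sid = f"{m['mouse_id']}-{comp.name}-d{day}"
        sample_ids.append(sid)
        f = np.array([t.fraction_in(comp.name) for t in taxa])
        expected = comp.baseline_load_cells_per_g * f
        if m["diet"] == Diet.FFD and day > 0:
            expected = expected * m_eff[comp.name]
        block_factors = _lognormal_sigma_factor(
            rng, config.block_factor_sigma, size=len(block_names)
        )
        taxon_noise = _lognormal_sigma_factor(rng, config.taxon_noise_sigma, size=n_taxa)
        loads = expected * mouse_mult[m["mouse_id"]] * np.asarray(block_factors)[block_of] * taxon_noise
        true_per_g[i] = loads
        density = float(loads.sum())

        wet = dry = None
        if comp.wet_weight_mean_g is not None:
            wet = float(
                comp.wet_weight_mean_g[m["diet"].value]
                * _lognormal_factor(rng, comp.wet_weight_cv)
            )
            dry_frac = comp.dry_fraction[m["diet"].value] if comp.dry_fraction else 0.2
            dry = wet * dry_frac
            true_per_comp[i] = loads * wet

        reps = [
            float(density * _lognormal_factor(rng, config.cellcount_cv))
            for _ in range(3)
        ]
        replicates[sid] = CellCountReplicates(sid, reps)

        if config.seq_depth_dispersion:
            k = config.seq_depth_dispersion
            depth = int(rng.negative_binomial(k, k / (k + config.seq_depth_mean)))
        else:
            depth = int(config.seq_depth_mean)
        counts[i] = sample_reads(loads, cvec, depth, rng)

        records.append(SampleRecord(
            sample_id=sid,
            mouse_id=m["mouse_id"],
            sex=m["sex"],
            diet=m["diet"],
            day=day,
            compartment=Compartment(comp.name),
            content_wet_weight_g=wet,
            content_dry_weight_g=dry,
            tissue_weight_g=None if wet is None else round(wet * 0.8, 6),
            body_weight_g=round(body_weight[m["mouse_id"]], 3),
            cell_density_cells_per_g=replicates[sid].mean,
        ))

        if config.tracer is not None and comp.wet_weight_mean_g is not None and day == 7:
            tr = config.tracer
            diet = m["diet"].value
            is_ctrl = m["is_tracer_control"]
            baseline = tr.control_atom_pct_13C * float(
                _lognormal_factor(rng, tr.measurement_cv)
            )
            excess = 0.0
            if not is_ctrl:
                excess = tr.labeled_excess_atom_pct[diet][comp.name] * float(
                    _lognormal_factor(rng, tr.measurement_cv)
                )
            atom13 = float(np.clip(baseline + excess, 0.0, 100.0))
            pct_c = float(tr.pct_C[diet][comp.name] * _lognormal_factor(rng, tr.measurement_cv))
            pct_n = float(tr.pct_N[diet][comp.name] * _lognormal_factor(rng, tr.measurement_cv))
            atom15 = float(
                NATURAL_ABUNDANCE_15N_ATOM_PCT * _lognormal_factor(rng, tr.measurement_cv)
            )
            tracer_measurements.append(TracerMeasurement(
                sample_id=sid,
                atom_pct_13C=atom13,
                atom_pct_15N=atom15,
                pct_C=min(pct_c, 100.0 - pct_n),
                pct_N=pct_n,
                dry_weight_mg=float(rng.uniform(0.05, 0.3)),
                is_control_12C=is_ctrl,
            ))

    read_table = TaxonReadTable(sample_ids, list(taxon_ids), counts)
    ground_truth = GroundTruth(
        true_load_per_g=pd.DataFrame(true_per_g, index=sample_ids, columns=taxon_ids),
        true_load_per_compartment=pd.DataFrame(
            true_per_comp, index=sample_ids, columns=taxon_ids
        ),
        true_total_density=pd.Series(true_per_g.sum(axis=1), index=sample_ids),
        guilds={t.taxon_id: t.guild for t in taxa},
        block_labels=blocks,
        l2fc=true_l2fc_table(config),
        flux=true_flux_table(config),
    )
    return SyntheticStudy(
        config=config,
        read_table=read_table,
        records=records,
        copy_numbers=config.copy_number_table(),
        cell_count_replicates=replicates,
        tracer_measurements=tracer_measurements,
        ground_truth=ground_truth,
    )


def simulate_ct_records(
    true_fold_change: float,
    sigma_ct: float,
    n_per_group: int,
    rng: np.random.Generator,
    reference_group: Diet = Diet.CD,
    treatment_group: Diet = Diet.FFD,
    ct_housekeeping_mean: float = 18.0,
    ct_target_mean: float = 24.0,
) -> list[CtRecord]:
    """Simulate qPCR cycle thresholds with a known expression fold change.

    The treatment group's target Ct is shifted by -log2(fold change)
    cycles; every Ct carries independent N(0, sigma_ct) noise.
    """
    if true_fold_change <= 0:
        raise ValueError("fold change must be > 0")
    shift = -np.log2(true_fold_change)
    out: list[CtRecord] = []
    for group, delta in ((reference_group, 0.0), (treatment_group, shift)):
        for i in range(n_per_group):
            out.append(CtRecord(
                sample_id=f"{group.value}q{i + 1:02d}",
                ct_target=float(ct_target_mean + delta + rng.normal(0, sigma_ct)),
                ct_housekeeping=float(ct_housekeeping_mean + rng.normal(0, sigma_ct)),
                group=group,
            ))
    return out


def write_synthetic_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Emit the study TSVs plus ground_truth.tsv, cell_counts.tsv, tracer.tsv."""
    from .data_model import write_study

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_study(study.read_table, study.records, study.copy_numbers, out)

    gt_long = (
        study.ground_truth.true_load_per_g.stack()
        .rename("true_load_per_g")
        .reset_index()
        .rename(columns={"level_0": "sample_id", "level_1": "taxon_id"})
    )
    gt_long["guild"] = gt_long["taxon_id"].map(study.ground_truth.guilds)
    paths["ground_truth"] = out / "ground_truth.tsv"
    gt_long.to_csv(paths["ground_truth"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    reps = pd.DataFrame([
        {"sample_id": sid, "replicate": j + 1, "cells_per_g": v}
        for sid, r in study.cell_count_replicates.items()
        for j, v in enumerate(r.replicate_counts_cells_per_g)
    ])
    paths["cell_counts"] = out / "cell_counts.tsv"
    reps.to_csv(paths["cell_counts"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    if study.tracer_measurements:
        tr = pd.DataFrame([vars(m) for m in study.tracer_measurements])
        paths["tracer"] = out / "tracer.tsv"
        tr.to_csv(paths["tracer"], sep="\t", index=False, float_format=FLOAT_FORMAT)
    return paths
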