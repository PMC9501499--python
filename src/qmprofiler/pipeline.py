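"""End-to-end pipeline: simulate/load -> profile -> analyze -> report.

Given a study (either on-disk TSVs or a synthetic scenario), runs the
full analysis with fixed seeds and writes one TSV per stage plus a
``run_manifest.json`` echoing the configuration. Every stage output
carries a ``# seed:`` header line; readers treat ``#`` lines as
comments, so outputs remain valid stage inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    Compartment,
    CopyNumberTable,
    Diet,
    SampleRecord,
    TaxonReadTable,
    filter_min_reads,
    read_study,
    records_by_id,
)
from .diff_guilds import (
    build_l2fc_report,
    guild_cluster_by_compartment,
    write_artifact_summary,
    write_guilds,
    write_l2fc_report,
)
from .diversity import (
    DEFAULT_RAREFACTION_DEPTH,
    alpha_diversity_table,
    bray_curtis_matrix,
    pcoa,
    permanova,
    write_diversity,
    write_ordination,
    write_permanova,
)
from .host_stats import anova_workflow, write_stats_report
from .qmp_core import profile_study, write_absolute_abundance
from .synthetic_data import generate_study, load_scenario, write_synthetic_study
from .tracer_physiology import TracerMeasurement, build_tracer_report, write_tracer_report

logger = logging.getLogger("qmprofiler")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the standard defaults."""

    scenario: str | Path | None = None      # scenario name/YAML, or...
    input_dir: str | Path | None = None     # ...directory with study TSVs
    out_dir: str | Path = "qmp_output"
    min_reads: int = 1000
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    top_k: int = 50
    pseudocount: float | str = "min_nonzero"
    alpha: float = 0.05
    permutations: int = 999
    k_range: tuple[int, int] = (2, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_reads", "rarefaction_depth", "top_k", "permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scenario is None and self.input_dir is None:
            raise ValueError("either a scenario or an input directory is required")


def _seed_header(path: Path, seed: int) -> None:
    text = path.read_text()
    path.write_text(f"# seed: {seed}\n" + text)


def _read_tracer_tsv(path: Path) -> list[TracerMeasurement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.to_dict(orient="records"):
        a15 = row.get("atom_pct_15N")
        out.append(TracerMeasurement(
            sample_id=str(row["sample_id"]),
            atom_pct_13C=float(row["atom_pct_13C"]),
            atom_pct_15N=None if a15 is None or pd.isna(a15) else float(a15),
            pct_C=float(row["pct_C"]),
            pct_N=float(row["pct_N"]),
            dry_weight_mg=float(row["dry_weight_mg"]),
            is_control_12C=bool(row.get("is_control_12C", False)),
        ))
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Deterministic for a fixed config (including seed). On a stage
    failure, partial outputs are kept and a FAILED marker file names the
    stage; the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage = "setup"
    t0 = time.perf_counter()
    try:
        tracer_measurements: list[TracerMeasurement] = []
        if config.scenario is not None:
            stage = "simulate"
            scenario = load_scenario(config.scenario)
            study = generate_study(scenario, seed=config.seed)
            write_synthetic_study(study, out)
            table, records, copynums = study.read_table, study.records, study.copy_numbers
            tracer_measurements = study.tracer_measurements
        else:
            stage = "load"
            d = Path(config.input_dir)
            table, records, copynums = read_study(
                d / "counts.tsv", d / "metadata.tsv", d / "copy_numbers.tsv"
            )
            if (d / "tracer.tsv").exists():
                tracer_measurements = _read_tracer_tsv(d / "tracer.tsv")
        _log_stage(stage, t0)

        stage = "profile"
        t0 = time.perf_counter()
        table = filter_min_reads(table, config.min_reads)
        abs_table = profile_study(table, records, copynums)
        write_absolute_abundance(abs_table, out / "absolute_abundance.tsv")
        _seed_header(out / "absolute_abundance.tsv", config.seed)
        _log_stage(stage, t0)

        stage = "diversity"
        t0 = time.perf_counter()
        deep = table.library_sizes() >= config.rarefaction_depth
        if not deep.all():
            shallow = [s for s, k in zip(table.sample_ids, deep) if not k]
            logger.warning(
                "%d samples below rarefaction depth %d excluded from alpha "
                "diversity: %s", len(shallow), config.rarefaction_depth,
                ", ".join(shallow),
            )
        alpha_ids = [s for s, k in zip(table.sample_ids, deep) if k]
        alpha_tab = alpha_diversity_table(
            alpha_ids, table.counts[deep], config.rarefaction_depth, rng
        )
        write_diversity(alpha_tab, out / "diversity.tsv")
        _seed_header(out / "diversity.tsv", config.seed)

        by_id = records_by_id(records)
        term_ids = [
            s for s in abs_table.sample_ids
            if by_id[s].compartment != Compartment.FECES and by_id[s].day == 7
        ]
        idx = [abs_table.sample_ids.index(s) for s in term_ids]
        rel = abs_table.rel_corrected[idx]
        dmat = bray_curtis_matrix(rel)
        ordination = pcoa(dmat, term_ids)
        write_ordination(ordination, out / "ordination.tsv")
        _seed_header(out / "ordination.tsv", config.seed)
        perm = permanova(
            dmat,
            {
                "diet": [by_id[s].diet.value for s in term_ids],
                "compartment": [by_id[s].compartment.value for s in term_ids],
            },
            n_permutations=config.permutations,
            rng=rng,
        )
        write_permanova(perm, out / "permanova.tsv")
        _seed_header(out / "permanova.tsv", config.seed)
        _log_stage(stage, t0)

        stage = "diffabund"
        t0 = time.perf_counter()
        report = build_l2fc_report(
            abs_table, records,
            top_k=config.top_k, pseudocount=config.pseudocount, alpha=config.alpha,
        )
        write_l2fc_report(report, out / "l2fc_report.tsv", pseudocount=config.pseudocount)
        _seed_header(out / "l2fc_report.tsv", config.seed)
        write_artifact_summary(report, out / "artifact_summary.txt")
        _log_stage(stage, t0)

        stage = "guilds"
        t0 = time.perf_counter()
        guilds = guild_cluster_by_compartment(
            abs_table, records, top_k=config.top_k,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
        )
        write_guilds(guilds, out / "guilds.tsv")
        _seed_header(out / "guilds.tsv", config.seed)
        _log_stage(stage, t0)

        if tracer_measurements:
            stage = "tracer"
            t0 = time.perf_counter()
            tracer_report = build_tracer_report(tracer_measurements, records)
            write_tracer_report(tracer_report, out / "tracer_report.tsv")
            _seed_header(out / "tracer_report.tsv", config.seed)
            _log_stage(stage, t0)
        else:
            tracer_report = None

        stage = "stats"
        t0 = time.perf_counter()
        stats_results = _endpoint_stats(alpha_tab, records, tracer_report, config)
        write_stats_report(stats_results, out / "stats_report.tsv")
        _seed_header(out / "stats_report.tsv", config.seed)
        _log_stage(stage, t0)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise

    manifest = {
        "qmprofiler_version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "notes": [
            "alpha diversity on counts rarefied at rarefaction_depth (seeded)",
            "beta diversity: Bray-Curtis on unrarefied corrected relative abundances",
            "Simpson reported as Gini-Simpson (1 - sum p^2)",
            "t-tests are Welch unless stated; multiple testing: Benjamini-Hochberg",
            "PERMANOVA: sequential sums of squares, factor order diet, compartment",
        ],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _log_stage(stage: str, t0: float) -> None:
    logger.info("stage %-10s %.2fs", stage, time.perf_counter() - t0)


def _endpoint_stats(alpha_tab, records, tracer_report, config):
    """The standard endpoint battery: alpha diversity, weights, water, flux."""
    by_id = records_by_id(records)
    results = []

    stool = alpha_tab[
        [by_id[s].compartment == Compartment.FECES for s in alpha_tab["sample_id"]]
    ]
    if len(stool) and stool["sample_id"].map(lambda s: by_id[s].day).nunique() >= 2:
        for metric in ("observed_richness", "shannon", "simpson"):
            try:
                results.append(anova_workflow(
                    stool[metric].to_numpy(),
                    [by_id[s].diet.value for s in stool["sample_id"]],
                    [by_id[s].day for s in stool["sample_id"]],
                    endpoint=f"stool_{metric}", factor_names=("diet", "day"),
                    alpha=config.alpha,
                ))
            except ValueError as exc:
                logger.warning("stats endpoint stool_%s skipped: %s", metric, exc)

    terminal = [
        r for r in records
        if r.compartment != Compartment.FECES and r.day == 7
        and r.content_wet_weight_g is not None
    ]
    if len({r.diet for r in terminal}) == 2 and len({r.compartment for r in terminal}) >= 2:
        for endpoint, getter in (
            ("content_wet_weight_g", lambda r: r.content_wet_weight_g),
            ("water_content_pct", lambda r: 100.0 * (r.content_wet_weight_g - r.content_dry_weight_g)
             / r.content_wet_weight_g if r.content_dry_weight_g is not None else None),
        ):
            vals = [(getter(r), r.diet.value, r.compartment.value) for r in terminal]
            vals = [v for v in vals if v[0] is not None]
            if len(vals) < 8:
                continue
            try:
                results.append(anova_workflow(
                    [v[0] for v in vals], [v[1] for v in vals], [v[2] for v in vals],
                    endpoint=endpoint, factor_names=("diet", "compartment"),
                    alpha=config.alpha,
                ))
            except ValueError as exc:
                logger.warning("stats endpoint %s skipped: %s", endpoint, exc)

    if tracer_report is not None:
        lab = tracer_report[~tracer_report["is_control_12C"]].dropna(
            subset=["flux_mg_13C_excess"]
        )
        if len(lab) >= 8 and lab["diet"].nunique() == 2 and lab["compartment"].nunique() >= 2:
            try:
                results.append(anova_workflow(
                    lab["flux_mg_13C_excess"].to_numpy(),
                    lab["diet"].to_numpy(), lab["compartment"].to_numpy(),
                    endpoint="secreted_carbon_flux", factor_names=("diet", "compartment"),
                    alpha=config.alpha,
                ))
            except ValueError as exc:
                logger.warning("stats endpoint flux skipped: %s", exc)
    return results
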