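"""Quantitative microbiome profiling (QMP).

Sequencing yields compositional data: read counts carry no information
about the total number of microbial cells in a sample. QMP rescales
copy-number-corrected relative abundances by an independently measured
total load (flow-cytometry cell density, cells/g) to recover absolute
taxon abundances, per gram of luminal content and — multiplied by the
weight of the content inside an intestinal compartment — per whole
compartment.

Per taxon j with read count r_j and 16S copy number c_j:

    rel_j  = (r_j / c_j) / sum_k (r_k / c_k)          (copy-number-corrected
                                                        relative abundance)
    a_j    = rel_j * density            [cells/g]
    A_j    = a_j * wet_weight           [cells/compartment]
    load   = sum_j A_j = density * wet_weight

Zero-read taxa get absolute abundance 0; no pseudocount is applied here
(pseudocounts belong to fold-change computation only), keeping detection
limits explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    FLOAT_FORMAT,
    Compartment,
    CopyNumberTable,
    SampleRecord,
    StudyValidationError,
    TaxonReadTable,
    UnsupportedCompartmentError,
    records_by_id,
)

__all__ = [
    "AbsoluteAbundanceTable",
    "copy_number_correct",
    "absolute_per_gram",
    "load_per_compartment",
    "sample_load",
    "profile_study",
    "write_absolute_abundance",
]


@dataclass
class AbsoluteAbundanceTable:
    """Copy-number-corrected relative and absolute abundances.

    ``abs_per_compartment`` entries are NaN for fecal samples, where no
    content weight exists and whole-compartment load is undefined.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    rel_corrected: np.ndarray       # samples x taxa, rows sum to 1
    abs_per_g: np.ndarray           # cells/g
    abs_per_compartment: np.ndarray  # cells per whole compartment (NaN for feces)

    @property
    def sample_load_per_compartment(self) -> np.ndarray:
        """Total cells per compartment, one entry per sample (NaN for feces)."""
        return self.abs_per_compartment.sum(axis=1)

    def frame(self, which: str = "abs_per_compartment") -> pd.DataFrame:
        return pd.DataFrame(
            getattr(self, which), index=self.sample_ids, columns=self.taxon_ids
        )


def copy_number_correct(reads: np.ndarray, copy_numbers: np.ndarray) -> np.ndarray:
    """Divide reads by per-taxon 16S copy number and renormalise to 1.

    Removes the amplification bias of multi-copy 16S operons: a genome
    with c rRNA operons contributes c reads per cell relative to a
    single-copy genome.
    """
    reads = np.asarray(reads, dtype=float)
    copy_numbers = np.asarray(copy_numbers, dtype=float)
    if reads.shape != copy_numbers.shape:
        raise ValueError("reads and copy_numbers must have the same length")
    if np.any(reads < 0):
        raise ValueError("negative read count")
    if np.any(copy_numbers <= 0):
        raise ValueError("copy numbers must be positive")
    corrected = reads / copy_numbers
    total = corrected.sum()
    if total <= 0:
        raise ValueError("cannot correct a sample with zero total reads")
    return corrected / total


def absolute_per_gram(rel_corrected: np.ndarray, cell_density_cells_per_g: float) -> np.ndarray:
    """Scale relative abundances by the flow-cytometry total density."""
    rel = np.asarray(rel_corrected, dtype=float)
    if cell_density_cells_per_g < 0:
        raise ValueError("cell density must be >= 0")
    if cell_density_cells_per_g > 0 and abs(rel.sum() - 1.0) > 1e-6:
        raise ValueError(f"relative abundances sum to {rel.sum()}, expected 1")
    return rel * cell_density_cells_per_g


def load_per_compartment(
    abs_per_g: np.ndarray,
    content_wet_weight_g: float,
    compartment: Compartment | str | None = None,
) -> np.ndarray:
    """Per-taxon cells in the whole compartment: abundance/g x grams of content."""
    if compartment is not None and Compartment(compartment) == Compartment.FECES:
        raise UnsupportedCompartmentError(
            "per-compartment load is undefined for feces (no content weight)"
        )
    if content_wet_weight_g < 0:
        raise ValueError("content weight must be >= 0")
    return np.asarray(abs_per_g, dtype=float) * content_wet_weight_g


def sample_load(abs_table: AbsoluteAbundanceTable) -> np.ndarray:
    """Total microbial load per sample, summed over taxa (cells/compartment)."""
    return abs_table.sample_load_per_compartment


def profile_study(
    table: TaxonReadTable,
    records: Sequence[SampleRecord],
    copy_numbers: CopyNumberTable,
) -> AbsoluteAbundanceTable:
    """Run the full QMP transform for every sample of a study.

    Every sample in the read table needs metadata with a cell density; a
    sample without one cannot be placed on the absolute scale and raises.
    """
    by_id = records_by_id(records)
    cvec = copy_numbers.vector_for(table.taxon_ids)
    n, p = table.n_samples, table.n_taxa
    rel = np.zeros((n, p))
    per_g = np.zeros((n, p))
    per_comp = np.full((n, p), np.nan)
    for i, sid in enumerate(table.sample_ids):
        rec = by_id.get(sid)
        if rec is None:
            raise StudyValidationError(f"sample {sid} has no metadata record")
        if rec.cell_density_cells_per_g is None:
            raise StudyValidationError(f"sample {sid} has no cell density")
        rel[i] = copy_number_correct(table.counts[i], cvec)
        per_g[i] = absolute_per_gram(rel[i], rec.cell_density_cells_per_g)
        if rec.compartment != Compartment.FECES:
            if rec.content_wet_weight_g is None:
                raise StudyValidationError(
                    f"sample {sid} ({rec.compartment.value}) has no content wet weight"
                )
            per_comp[i] = load_per_compartment(
                per_g[i], rec.content_wet_weight_g, rec.compartment
            )
    return AbsoluteAbundanceTable(
        list(table.sample_ids), list(table.taxon_ids), rel, per_g, per_comp
    )


def write_absolute_abundance(abs_table: AbsoluteAbundanceTable, path: str | Path) -> None:
    """Emit absolute_abundance.tsv in long form."""
    n, p = abs_table.rel_corrected.shape
    df = pd.DataFrame({
        "sample_id": np.repeat(abs_table.sample_ids, p),
        "taxon_id": np.tile(abs_table.taxon_ids, n),
        "rel_corrected": abs_table.rel_corrected.ravel(),
        "abs_per_g": abs_table.abs_per_g.ravel(),
        "abs_per_compartment": abs_table.abs_per_compartment.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
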