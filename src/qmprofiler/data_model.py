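"""Core domain types and TSV readers/writers shared by all pipeline stages.

The on-disk study format is three tab-separated files:

``counts.tsv``
    First column ``taxon_id``, remaining columns one per sample, integer
    read counts (taxa as rows, samples as columns).
``metadata.tsv``
    One row per sample with the columns listed in
    :data:`METADATA_COLUMNS`.
``copy_numbers.tsv``
    Columns ``taxon_id`` and ``copy_number`` (16S rRNA gene copies per
    genome, from a reference such as rrnDB).

In memory, read counts are held samples x taxa.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("qmprofiler")

#: Floating-point values are serialised with this many significant digits,
#: enough for a bit-stable round-trip of every quantity the pipeline emits.
FLOAT_FORMAT = "%.12g"

METADATA_COLUMNS = [
    "sample_id",
    "mouse_id",
    "sex",
    "diet",
    "day",
    "compartment",
    "content_wet_weight_g",
    "content_dry_weight_g",
    "tissue_weight_g",
    "body_weight_g",
    "cell_density_cells_per_g",
]

VALID_DAYS = (0, 2, 7)


class StudyValidationError(ValueError):
    """A study object or its on-disk representation violates an invariant."""


class EmptyStudyError(StudyValidationError):
    """An operation removed every sample from the study."""


class UnsupportedCompartmentError(StudyValidationError):
    """An operation was applied to a compartment it is undefined for."""


class Diet(str, enum.Enum):
    CD = "CD"    # control chow diet
    FFD = "FFD"  # fiber-free diet

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Compartment(str, enum.Enum):
    SMALL_INTESTINE = "small_intestine"
    CECUM = "cecum"
    COLON = "colon"
    FECES = "feces"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Terminal gut compartments for which a whole-compartment load is defined.
#: Feces carry no content weight, so per-compartment load is undefined there.
INTESTINAL_COMPARTMENTS = (
    Compartment.SMALL_INTESTINE,
    Compartment.CECUM,
    Compartment.COLON,
)


@dataclass
class TaxonReadTable:
    """Integer 16S read counts, samples x genera.

    ``counts`` rows are samples, columns are taxa. A zero library size is
    representable but logged as a warning at construction.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise StudyValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise StudyValidationError("read counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise StudyValidationError("read counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StudyValidationError("duplicate sample_id in read table")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise StudyValidationError("duplicate taxon_id in read table")
        empty = [s for s, n in zip(self.sample_ids, self.library_sizes()) if n == 0]
        if empty:
            logger.warning("samples with zero reads: %s", ", ".join(empty))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def library_sizes(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonReadTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return TaxonReadTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])


@dataclass
class SampleRecord:
    """Per-sample metadata and physical measurements."""

    sample_id: str
    mouse_id: str
    sex: str
    diet: Diet
    day: int
    compartment: Compartment
    content_wet_weight_g: float | None = None
    content_dry_weight_g: float | None = None
    tissue_weight_g: float | None = None
    body_weight_g: float | None = None
    cell_density_cells_per_g: float | None = None

    def __post_init__(self) -> None:
        self.diet = Diet(self.diet)
        self.compartment = Compartment(self.compartment)
        self.day = int(self.day)
        if self.day not in VALID_DAYS:
            raise StudyValidationError(
                f"sample {self.sample_id}: day {self.day} not in {VALID_DAYS}"
            )
        for name in ("content_wet_weight_g", "content_dry_weight_g", "tissue_weight_g",
                     "cell_density_cells_per_g"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise StudyValidationError(f"sample {self.sample_id}: {name} < 0")
        if self.body_weight_g is not None and self.body_weight_g <= 0:
            raise StudyValidationError(f"sample {self.sample_id}: body_weight_g <= 0")
        if (
            self.content_wet_weight_g is not None
            and self.content_dry_weight_g is not None
            and self.content_dry_weight_g > self.content_wet_weight_g + 1e-12
        ):
            raise StudyValidationError(
                f"sample {self.sample_id}: dry weight "
                f"{self.content_dry_weight_g} exceeds wet weight "
                f"{self.content_wet_weight_g}"
            )


@dataclass
class CopyNumberTable:
    """Per-taxon 16S rRNA gene copy numbers.

    A taxon absent from the table falls back to ``default`` (1.0 means no
    correction) with a logged warning; ``default=None`` makes a missing
    taxon a hard error.
    """

    copy_numbers: dict[str, float]
    default: float | None = 1.0

    def __post_init__(self) -> None:
        for taxon, c in self.copy_numbers.items():
            if not c >= 1:
                raise StudyValidationError(
                    f"copy number for {taxon} must be >= 1, got {c}"
                )
        if self.default is not None and not self.default >= 1:
            raise StudyValidationError("default copy number must be >= 1")

    def vector_for(self, taxon_ids: Sequence[str]) -> np.ndarray:
        missing = [t for t in taxon_ids if t not in self.copy_numbers]
        if missing:
            if self.default is None:
                raise StudyValidationError(
                    "no copy number and no default for taxa: " + ", ".join(missing)
                )
            logger.warning(
                "using default copy number %.3g for %d taxa: %s",
                self.default, len(missing), ", ".join(missing),
            )
        return np.array(
            [self.copy_numbers.get(t, self.default) for t in taxon_ids], dtype=float
        )


@dataclass
class CellCountReplicates:
    """Flow-cytometry triplicate cell densities for one sample (cells/g)."""

    sample_id: str
    replicate_counts_cells_per_g: list[float]

    def __post_init__(self) -> None:
        if len(self.replicate_counts_cells_per_g) < 1:
            raise StudyValidationError(
                f"sample {self.sample_id}: at least one replicate required"
            )
        if any(v < 0 for v in self.replicate_counts_cells_per_g):
            raise StudyValidationError(
                f"sample {self.sample_id}: negative replicate count"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_counts_cells_per_g))


def validate_replicates(
    records: Sequence[SampleRecord],
    replicates: Mapping[str, CellCountReplicates],
    rtol: float = 1e-6,
) -> None:
    """Check that each record's cell density is the mean of its replicates."""
    for rec in records:
        if rec.sample_id in replicates and rec.cell_density_cells_per_g is not None:
            m = replicates[rec.sample_id].mean
            if not math.isclose(m, rec.cell_density_cells_per_g, rel_tol=rtol, abs_tol=1e-9):
                raise StudyValidationError(
                    f"sample {rec.sample_id}: cell density "
                    f"{rec.cell_density_cells_per_g} is not the replicate mean {m}"
                )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise StudyValidationError(f"malformed TSV {path}: {exc}") from exc


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_counts(path: str | Path) -> TaxonReadTable:
    df = _read_tsv(path)
    if df.columns[0] != "taxon_id":
        raise StudyValidationError(
            f"{path}: first column must be 'taxon_id', got {df.columns[0]!r}"
        )
    taxon_ids = df["taxon_id"].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    counts = df.iloc[:, 1:].to_numpy().T  # disk is taxa x samples
    return TaxonReadTable(sample_ids, taxon_ids, counts)


def read_metadata(path: str | Path) -> list[SampleRecord]:
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise StudyValidationError(f"{path}: missing metadata columns: {', '.join(missing)}")
    records = []
    for row in df.to_dict(orient="records"):
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                mouse_id=str(row["mouse_id"]),
                sex=str(row["sex"]),
                diet=Diet(row["diet"]),
                day=int(row["day"]),
                compartment=Compartment(row["compartment"]),
                content_wet_weight_g=_opt(row.get("content_wet_weight_g")),
                content_dry_weight_g=_opt(row.get("content_dry_weight_g")),
                tissue_weight_g=_opt(row.get("tissue_weight_g")),
                body_weight_g=_opt(row.get("body_weight_g")),
                cell_density_cells_per_g=_opt(row.get("cell_density_cells_per_g")),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise StudyValidationError(f"{path}: duplicate sample_id: {', '.join(dupes)}")
    return records


def read_copy_numbers(path: str | Path, default: float | None = 1.0) -> CopyNumberTable:
    df = _read_tsv(path)
    for col in ("taxon_id", "copy_number"):
        if col not in df.columns:
            raise StudyValidationError(f"{path}: missing column {col!r}")
    return CopyNumberTable(
        dict(zip(df["taxon_id"].astype(str), df["copy_number"].astype(float))),
        default=default,
    )


def read_study(
    count_table_path: str | Path,
    metadata_path: str | Path,
    copy_number_path: str | Path,
    copy_number_default: float | None = 1.0,
) -> tuple[TaxonReadTable, list[SampleRecord], CopyNumberTable]:
    """Read and cross-validate the three study TSVs.

    Samples present in the count table but absent from the metadata are
    rejected; metadata rows without counts are allowed (e.g. samples that
    failed sequencing) and logged.
    """
    table = read_counts(count_table_path)
    records = read_metadata(metadata_path)
    copynums = read_copy_numbers(copy_number_path, default=copy_number_default)
    meta_ids = {r.sample_id for r in records}
    orphans = [s for s in table.sample_ids if s not in meta_ids]
    if orphans:
        raise StudyValidationError(
            "samples in count table without metadata: " + ", ".join(orphans)
        )
    unsequenced = meta_ids - set(table.sample_ids)
    if unsequenced:
        logger.info("metadata samples without counts: %s", ", ".join(sorted(unsequenced)))
    copynums.vector_for(table.taxon_ids)  # force the missing-taxon check now
    return table, records, copynums


def write_counts(table: TaxonReadTable, path: str | Path) -> None:
    df = table.to_frame().T  # disk layout: taxa x samples
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "mouse_id": r.mouse_id,
            "sex": r.sex,
            "diet": r.diet.value,
            "day": r.day,
            "compartment": r.compartment.value,
            "content_wet_weight_g": r.content_wet_weight_g,
            "content_dry_weight_g": r.content_dry_weight_g,
            "tissue_weight_g": r.tissue_weight_g,
            "body_weight_g": r.body_weight_g,
            "cell_density_cells_per_g": r.cell_density_cells_per_g,
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_copy_numbers(copynums: CopyNumberTable, path: str | Path) -> None:
    pd.DataFrame(
        {"taxon_id": list(copynums.copy_numbers), "copy_number": list(copynums.copy_numbers.values())}
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_study(
    table: TaxonReadTable,
    records: Sequence[SampleRecord],
    copynums: CopyNumberTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv / metadata.tsv / copy_numbers.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "copy_numbers": out / "copy_numbers.tsv",
    }
    write_counts(table, paths["counts"])
    write_metadata(records, paths["metadata"])
    write_copy_numbers(copynums, paths["copy_numbers"])
    return paths


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_min_reads(table: TaxonReadTable, min_reads: int = 1000) -> TaxonReadTable:
    """Drop samples with fewer than ``min_reads`` total reads.

    The default threshold of 1000 reads matches the pipeline's standard
    sequencing-depth subset. The taxon set is unchanged; the operation is
    idempotent.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.library_sizes() >= min_reads
    if not keep.any():
        raise EmptyStudyError(
            f"no sample reaches {min_reads} reads (max library size "
            f"{int(table.library_sizes().max()) if table.n_samples else 0})"
        )
    kept = [s for s, k in zip(table.sample_ids, keep) if k]
    return TaxonReadTable(kept, list(table.taxon_ids), table.counts[keep])


def records_by_id(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}
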