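"""Stable-isotope tracer flux, elemental stoichiometry, and qPCR expression.

Mucus secretion is quantified by injecting mice intravenously with
13C/15N-labeled L-threonine: the threonine-rich domain of the Muc2 mucin
incorporates the tracer, so 13C enrichment of washed luminal biomass
(measured by EA-IRMS) reads out mucus secreted into the gut lumen.

The secreted-carbon flux per compartment is the product of the 13C atom
fraction excess over the unlabeled baseline, the carbon content of the
biomass, and the dry weight of the compartment's luminal contents:

    flux [mg 13C-excess] = AFE * (%C / 100) * dry_weight_mg

Unlabeled-threonine control animals define the baseline atom% 13C; when no
controls are available the natural-abundance constant 1.07 atom% is used.
15N values are carried in reports but do not enter the flux formula.

The module also computes C:N ratios, water content of luminal material,
and 2^-ddCt relative gene expression (muc2 normalized to the 36B4
housekeeping gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import FLOAT_FORMAT, Diet, SampleRecord, records_by_id

logger = logging.getLogger("qmprofiler")

#: Natural abundance of 13C (atom %), the fallback baseline when no
#: unlabeled-control animals were measured.
NATURAL_ABUNDANCE_13C_ATOM_PCT = 1.07

#: qPCR cycle ceiling; Ct values at or above this are non-detections.
CT_CEILING = 40.0


@dataclass
class TracerMeasurement:
    """One EA-IRMS measurement of washed, dried luminal biomass."""

    sample_id: str
    atom_pct_13C: float
    pct_C: float
    pct_N: float
    dry_weight_mg: float
    atom_pct_15N: float | None = None
    is_control_12C: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.atom_pct_13C <= 100:
            raise ValueError(f"{self.sample_id}: atom% 13C out of [0, 100]")
        if self.atom_pct_15N is not None and not 0 <= self.atom_pct_15N <= 100:
            raise ValueError(f"{self.sample_id}: atom% 15N out of [0, 100]")
        if not 0 <= self.pct_C <= 100:
            raise ValueError(f"{self.sample_id}: %C out of [0, 100]")
        if not 0 < self.pct_N <= 100:
            raise ValueError(f"{self.sample_id}: %N out of (0, 100]")
        if self.pct_C + self.pct_N > 100:
            raise ValueError(f"{self.sample_id}: %C + %N exceeds 100")
        if not self.dry_weight_mg > 0:
            raise ValueError(f"{self.sample_id}: dry weight must be > 0")


@dataclass
class CtRecord:
    """qPCR cycle thresholds for target (muc2) and housekeeping (36B4) genes."""

    sample_id: str
    ct_target: float
    ct_housekeeping: float
    group: Diet

    def __post_init__(self) -> None:
        self.group = Diet(self.group)
        for name, ct in (("ct_target", self.ct_target), ("ct_housekeeping", self.ct_housekeeping)):
            if not 0 < ct < CT_CEILING:
                raise ValueError(
                    f"{self.sample_id}: {name}={ct} outside (0, {CT_CEILING})"
                )


def atom_fraction_excess(sample_atom_pct: float, baseline_atom_pct: float) -> float:
    """Isotopic enrichment above baseline, as a dimensionless atom fraction.

    A sample below baseline (measurement noise on an unlabeled sample)
    clamps to 0 with a warning rather than reporting negative enrichment.
    """
    if not 0 <= sample_atom_pct <= 100 or not 0 <= baseline_atom_pct <= 100:
        raise ValueError("atom percentages must lie in [0, 100]")
    excess = (sample_atom_pct - baseline_atom_pct) / 100.0
    if excess < 0:
        logger.warning(
            "negative atom%% excess (%.4g below baseline) clamped to 0",
            baseline_atom_pct - sample_atom_pct,
        )
        return 0.0
    return excess


def baseline_from_controls(measurements: Iterable[TracerMeasurement]) -> float:
    """Mean atom% 13C of the unlabeled-control animals.

    Falls back to the natural-abundance constant when no controls exist.
    """
    controls = [m.atom_pct_13C for m in measurements if m.is_control_12C]
    if not controls:
        logger.warning(
            "no 12C-control animals; using natural abundance %.2f atom%%",
            NATURAL_ABUNDANCE_13C_ATOM_PCT,
        )
        return NATURAL_ABUNDANCE_13C_ATOM_PCT
    return float(np.mean(controls))


def secreted_carbon_flux(afe_13C: float, pct_C: float, dry_weight_mg: float) -> float:
    """Secreted 13C-excess mass per compartment (mg).

    ``dry_weight_mg`` is the dry weight of the whole compartment's luminal
    contents, so the flux integrates enrichment over the compartment.
    """
    if not 0 <= afe_13C <= 1:
        raise ValueError("atom fraction excess must lie in [0, 1]")
    if not 0 <= pct_C <= 100:
        raise ValueError("%C must lie in [0, 100]")
    if not dry_weight_mg > 0:
        raise ValueError("dry weight must be > 0")
    return afe_13C * (pct_C / 100.0) * dry_weight_mg


def cn_ratio(pct_C: float, pct_N: float) -> float:
    """Carbon-to-nitrogen mass ratio of bulk biomass."""
    if pct_N <= 0:
        raise ValueError("%N must be > 0")
    return pct_C / pct_N


def water_content(wet_g: float, dry_g: float) -> float:
    """Water content of luminal material, percent of wet weight."""
    if wet_g <= 0:
        raise ValueError("wet weight must be > 0")
    if dry_g > wet_g:
        raise ValueError("dry weight exceeds wet weight")
    if dry_g < 0:
        raise ValueError("dry weight must be >= 0")
    return float(np.clip(100.0 * (wet_g - dry_g) / wet_g, 0.0, 100.0))


def ddct_fold_change(
    records: Sequence[CtRecord],
    reference_group: Diet | str = Diet.CD,
) -> float:
    """Relative expression of the treatment group by the 2^-ddCt method.

    dCt = Ct(target) - Ct(housekeeping) per sample; ddCt is the mean dCt
    of the treatment group minus the mean dCt of the reference group; the
    fold change is 2^-ddCt (1 = no change, <1 = reduced expression).
    """
    reference_group = Diet(reference_group)
    dct: dict[Diet, list[float]] = {}
    for r in records:
        dct.setdefault(r.group, []).append(r.ct_target - r.ct_housekeeping)
    if reference_group not in dct:
        raise ValueError(f"no records for reference group {reference_group.value}")
    treatment = [g for g in dct if g != reference_group]
    if len(treatment) != 1:
        raise ValueError(
            f"expected exactly one treatment group, got {[g.value for g in treatment]}"
        )
    ddct = float(np.mean(dct[treatment[0]]) - np.mean(dct[reference_group]))
    return 2.0 ** (-ddct)


def build_tracer_report(
    measurements: Sequence[TracerMeasurement],
    records: Sequence[SampleRecord],
    baseline_atom_pct: float | None = None,
) -> pd.DataFrame:
    """Per-sample AFE, secreted-carbon flux, C:N, %C, and water content.

    The flux uses the whole-compartment dry content weight
    (``content_dry_weight_g`` x 1000, in mg) from the sample metadata; the
    EA-IRMS aliquot mass is reported but does not enter the flux.
    """
    if baseline_atom_pct is None:
        baseline_atom_pct = baseline_from_controls(measurements)
    by_id = records_by_id(records)
    rows = []
    for m in measurements:
        rec = by_id.get(m.sample_id)
        afe = atom_fraction_excess(m.atom_pct_13C, baseline_atom_pct)
        row = {
            "sample_id": m.sample_id,
            "is_control_12C": m.is_control_12C,
            "atom_pct_13C": m.atom_pct_13C,
            "atom_pct_15N": m.atom_pct_15N,
            "afe_13C": afe,
            "pct_C": m.pct_C,
            "pct_N": m.pct_N,
            "cn_ratio": cn_ratio(m.pct_C, m.pct_N),
            "baseline_atom_pct_13C": baseline_atom_pct,
            "diet": rec.diet.value if rec else None,
            "compartment": rec.compartment.value if rec else None,
            "flux_mg_13C_excess": None,
            "water_content_pct": None,
        }
        if rec is not None and rec.content_dry_weight_g is not None:
            row["flux_mg_13C_excess"] = secreted_carbon_flux(
                afe, m.pct_C, rec.content_dry_weight_g * 1000.0
            ) if rec.content_dry_weight_g > 0 else 0.0
            if rec.content_wet_weight_g and rec.content_wet_weight_g > 0:
                row["water_content_pct"] = water_content(
                    rec.content_wet_weight_g, rec.content_dry_weight_g
                )
        rows.append(row)
    return pd.DataFrame(rows)


def write_tracer_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def build_expression_report(
    records: Sequence[CtRecord],
    reference_group: Diet | str = Diet.CD,
) -> pd.DataFrame:
    """Single-row fold-change summary for one target gene."""
    reference_group = Diet(reference_group)
    fc = ddct_fold_change(records, reference_group)
    groups = sorted({r.group.value for r in records})
    return pd.DataFrame([{
        "reference_group": reference_group.value,
        "treatment_group": next(g for g in groups if g != reference_group.value),
        "n_samples": len(records),
        "fold_change_2_neg_ddct": fc,
        "log2_fold_change": float(np.log2(fc)),
    }])
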