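"""Differential abundance on absolute vs. relative scales, artifact
flagging, concordance, and co-abundance guild clustering.

The central comparison: for the top genera of each intestinal
compartment, the log2 fold change between diets (FFD/CD) is computed
twice — on absolute abundances (cells per compartment, from quantitative
profiling) and on relative abundances. When total microbial load differs
between groups, the two scales disagree systematically: a taxon whose
absolute load is unchanged while the community collapses by a factor rho
shows a relative log2 fold change of -log2(rho) with zero absolute
change. Such taxa are flagged as compositional artifacts
(``relative_only_increase``/``relative_only_decrease``), the
quantitative-profiling signature of a "pseudo-bloom".

Guilds — groups of taxa with concordant dynamics — are found by Ward
clustering of 1 - Spearman correlation between taxon abundance profiles,
with the cluster count chosen by maximal mean silhouette width, and
overall agreement of taxon rankings quantified by Kendall's coefficient
of concordance W.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .data_model import (
    FLOAT_FORMAT,
    Compartment,
    Diet,
    INTESTINAL_COMPARTMENTS,
    SampleRecord,
    records_by_id,
)
from .qmp_core import AbsoluteAbundanceTable

logger = logging.getLogger("qmprofiler")

__all__ = [
    "DEFAULT_TOP_K",
    "ArtifactFlag",
    "L2FCRecord",
    "GuildResult",
    "select_top_taxa",
    "l2fc",
    "diet_test",
    "build_l2fc_report",
    "report_to_frame",
    "kendall_concordance",
    "guild_cluster",
]

#: Number of most-abundant genera carried into the fold-change comparison.
DEFAULT_TOP_K = 50


class ArtifactFlag(str, enum.Enum):
    NONE = "none"
    RELATIVE_ONLY_INCREASE = "relative_only_increase"
    RELATIVE_ONLY_DECREASE = "relative_only_decrease"
    DISCORDANT_SIGN = "discordant_sign"


@dataclass
class L2FCRecord:
    taxon_id: str
    compartment: str
    l2fc_absolute: float
    l2fc_relative: float
    p_absolute: float
    p_relative: float
    significant_absolute: bool
    significant_relative: bool
    artifact_flag: ArtifactFlag


@dataclass
class GuildResult:
    compartment: str
    k_selected: int
    assignments: dict[str, int]          # taxon -> cluster label (1-based)
    silhouette_by_k: dict[int, float]
    kendall_w: float
    kendall_p: float
    cluster_diet_tests: pd.DataFrame     # per-cluster per-diet totals and t-test p
    dropped_taxa: list[str] = field(default_factory=list)


def select_top_taxa(
    abundances: pd.DataFrame,
    k: int = DEFAULT_TOP_K,
) -> list[str]:
    """Taxa ranked by mean abundance over all samples (diets pooled).

    Ties break lexicographically by taxon id. If fewer than ``k`` taxa
    exist, all are returned with a warning.
    """
    if abundances.shape[1] == 0 or abundances.shape[0] == 0:
        raise ValueError("empty abundance table")
    means = abundances.mean(axis=0)
    if len(means) < k:
        logger.warning("only %d taxa available for top-%d selection", len(means), k)
        k = len(means)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:k]


def l2fc(
    values_ffd: np.ndarray,
    values_cd: np.ndarray,
    pseudocount: float,
) -> float:
    """log2((mean FFD + pc) / (mean CD + pc)); the pseudocount keeps it finite."""
    values_ffd = np.asarray(values_ffd, dtype=float)
    values_cd = np.asarray(values_cd, dtype=float)
    if np.any(values_ffd < 0) or np.any(values_cd < 0):
        raise ValueError("abundances must be non-negative")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((values_ffd.mean() + pseudocount) / (values_cd.mean() + pseudocount)))


def diet_test(
    values_ffd: np.ndarray,
    values_cd: np.ndarray,
    equal_var: bool = False,
) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    Returns NaN with a warning when a group has fewer than 2 samples.
    Identical groups (zero pooled variance, zero difference) return 1.
    """
    values_ffd = np.asarray(values_ffd, dtype=float)
    values_cd = np.asarray(values_cd, dtype=float)
    if len(values_ffd) < 2 or len(values_cd) < 2:
        logger.warning("diet_test: fewer than 2 samples per diet; returning NaN")
        return float("nan")
    if np.var(values_ffd) == 0 and np.var(values_cd) == 0:
        return 1.0 if values_ffd.mean() == values_cd.mean() else 0.0
    res = stats.ttest_ind(values_ffd, values_cd, equal_var=equal_var)
    return float(res.pvalue)


def _classify(
    l2fc_rel: float, sig_rel: bool, l2fc_abs: float, sig_abs: bool
) -> ArtifactFlag:
    if sig_rel and not sig_abs:
        if l2fc_rel > 0:
            return ArtifactFlag.RELATIVE_ONLY_INCREASE
        if l2fc_rel < 0:
            return ArtifactFlag.RELATIVE_ONLY_DECREASE
    if sig_rel and sig_abs and l2fc_rel * l2fc_abs < 0:
        return ArtifactFlag.DISCORDANT_SIGN
    return ArtifactFlag.NONE


def _adjust(pvals: np.ndarray, method: str, alpha: float) -> np.ndarray:
    ok = np.isfinite(pvals)
    sig = np.zeros(len(pvals), dtype=bool)
    if ok.sum():
        sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
        sig[ok] = multipletests(pvals[ok], alpha=alpha, method=sm_method)[0]
    return sig


def _pseudocount_for(matrix: pd.DataFrame, policy: float | str) -> float:
    if isinstance(policy, (int, float)):
        return float(policy)
    if policy == "min_nonzero":
        vals = matrix.to_numpy()
        nz = vals[vals > 0]
        if nz.size == 0:
            return 1.0
        return float(nz.min())
    raise ValueError(f"unknown pseudocount policy {policy!r}")


def build_l2fc_report(
    abs_table: AbsoluteAbundanceTable,
    records: Sequence[SampleRecord],
    top_k: int = DEFAULT_TOP_K,
    pseudocount: float | str = "min_nonzero",
    alpha: float = 0.05,
    correction: str = "bh",
    equal_var: bool = False,
    day: int = 7,
) -> list[L2FCRecord]:
    """Per-compartment fold changes of the top taxa on both scales.

    Top-taxa selection uses mean absolute (per-compartment) abundance
    pooled over both diets. Significance per scale is a two-sample t-test
    across the top taxa with multiple-testing correction (Benjamini-
    Hochberg by default, Bonferroni optional). Feces (no compartment
    load) and compartments observed under a single diet are skipped with
    a warning.
    """
    by_id = records_by_id(records)
    abs_frame = abs_table.frame("abs_per_compartment")
    rel_frame = abs_table.frame("rel_corrected")
    out: list[L2FCRecord] = []
    for comp in INTESTINAL_COMPARTMENTS:
        sids = [
            s for s in abs_table.sample_ids
            if by_id[s].compartment == comp and by_id[s].day == day
        ]
        diets = {by_id[s].diet for s in sids}
        if not sids or len(diets) < 2:
            if sids:
                logger.warning("%s: only one diet present; skipped", comp.value)
            continue
        ffd = [s for s in sids if by_id[s].diet == Diet.FFD]
        cd = [s for s in sids if by_id[s].diet == Diet.CD]
        comp_abs = abs_frame.loc[sids]
        comp_rel = rel_frame.loc[sids]
        top = select_top_taxa(comp_abs, top_k)
        pc_abs = _pseudocount_for(comp_abs[top], pseudocount)
        pc_rel = _pseudocount_for(comp_rel[top], pseudocount)

        rows = []
        for taxon in top:
            a_f, a_c = comp_abs.loc[ffd, taxon].to_numpy(), comp_abs.loc[cd, taxon].to_numpy()
            r_f, r_c = comp_rel.loc[ffd, taxon].to_numpy(), comp_rel.loc[cd, taxon].to_numpy()
            rows.append({
                "taxon_id": taxon,
                "l2fc_absolute": l2fc(a_f, a_c, pc_abs),
                "l2fc_relative": l2fc(r_f, r_c, pc_rel),
                "p_absolute": diet_test(a_f, a_c, equal_var=equal_var),
                "p_relative": diet_test(r_f, r_c, equal_var=equal_var),
            })
        df = pd.DataFrame(rows)
        sig_abs = _adjust(df["p_absolute"].to_numpy(), correction, alpha)
        sig_rel = _adjust(df["p_relative"].to_numpy(), correction, alpha)
        for row, sa, sr in zip(rows, sig_abs, sig_rel):
            out.append(L2FCRecord(
                taxon_id=row["taxon_id"],
                compartment=comp.value,
                l2fc_absolute=row["l2fc_absolute"],
                l2fc_relative=row["l2fc_relative"],
                p_absolute=row["p_absolute"],
                p_relative=row["p_relative"],
                significant_absolute=bool(sa),
                significant_relative=bool(sr),
                artifact_flag=_classify(
                    row["l2fc_relative"], bool(sr), row["l2fc_absolute"], bool(sa)
                ),
            ))
    return out


def report_to_frame(report: Sequence[L2FCRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "taxon_id": r.taxon_id,
            "compartment": r.compartment,
            "l2fc_absolute": r.l2fc_absolute,
            "l2fc_relative": r.l2fc_relative,
            "p_absolute": r.p_absolute,
            "p_relative": r.p_relative,
            "significant_absolute": r.significant_absolute,
            "significant_relative": r.significant_relative,
            "artifact_flag": r.artifact_flag.value,
        }
        for r in report
    ])


def write_l2fc_report(
    report: Sequence[L2FCRecord],
    path: str | Path,
    correction: str = "bh",
    pseudocount: float | str = "min_nonzero",
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# multiple-testing correction: {correction}; "
                 f"pseudocount policy: {pseudocount}\n")
        report_to_frame(report).to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Concordance and guild clustering
# ---------------------------------------------------------------------------

def kendall_concordance(abundances: np.ndarray) -> tuple[float, float]:
    """Kendall's coefficient of concordance W across taxa (judges).

    Rows are taxa ranking the samples (objects) by abundance; ties get
    midranks with the standard tie correction. Significance is the
    chi-square approximation chi2 = m (n - 1) W with n - 1 df.
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("need at least 2 taxa and 2 samples")
    if np.all(np.ptp(a, axis=1) == 0):
        raise ValueError("Kendall's W undefined for a constant matrix")
    m, n = a.shape
    ranks = np.vstack([stats.rankdata(row) for row in a])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in a:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts ** 3 - counts).sum())
    denom = m ** 2 * (n ** 3 - n) / 12.0 - m * tie_term / 12.0
    if denom <= 0:
        raise ValueError("Kendall's W undefined: all rankings fully tied")
    w = s / denom
    w = min(max(w, 0.0), 1.0)
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df=n - 1))
    return w, p


def guild_cluster(
    abundances: pd.DataFrame,
    records: Sequence[SampleRecord] | None = None,
    compartment: str = "",
    k_range: Sequence[int] = range(2, 9),
    equal_var: bool = False,
) -> GuildResult:
    """Ward clustering of taxa on 1 - Spearman correlation distances.

    ``abundances`` is samples x taxa (absolute scale) for one
    compartment, both diets pooled. The cluster count k maximises the
    mean silhouette width over ``k_range``. Constant taxon profiles have
    undefined correlations and are dropped with a warning. When sample
    metadata are supplied, per-cluster total abundances are compared
    between diets by t-test.
    """
    a = abundances.copy()
    const = [t for t in a.columns if np.ptp(a[t].to_numpy()) == 0]
    if const:
        logger.warning("dropping %d constant taxon profiles: %s",
                       len(const), ", ".join(const))
        a = a.drop(columns=const)
    k_range = [int(k) for k in k_range]
    if a.shape[1] < max(k_range) + 1:
        raise ValueError(
            f"need at least {max(k_range) + 1} non-constant taxa, have {a.shape[1]}"
        )
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples")

    rho = stats.spearmanr(a.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")

    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        labels = fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            sil[k] = float("-inf")
        else:
            sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    k_selected = max(sorted(sil), key=lambda k: sil[k])
    labels = labels_by_k[k_selected]
    assignments = dict(zip(a.columns, (int(v) for v in labels)))

    w, wp = kendall_concordance(a.to_numpy().T)

    diet_rows = []
    if records is not None:
        by_id = records_by_id(records)
        diet_of = np.array([by_id[s].diet.value for s in a.index])
        for cl in sorted(set(labels)):
            members = [t for t, lab in assignments.items() if lab == cl]
            totals = a[members].sum(axis=1).to_numpy()
            ffd, cd = totals[diet_of == "FFD"], totals[diet_of == "CD"]
            diet_rows.append({
                "compartment": compartment,
                "cluster": cl,
                "n_taxa": len(members),
                "mean_total_CD": float(cd.mean()) if len(cd) else float("nan"),
                "mean_total_FFD": float(ffd.mean()) if len(ffd) else float("nan"),
                "p_diet": diet_test(ffd, cd, equal_var=equal_var)
                if len(ffd) >= 2 and len(cd) >= 2 else float("nan"),
            })
    return GuildResult(
        compartment=compartment,
        k_selected=int(k_selected),
        assignments=assignments,
        silhouette_by_k=sil,
        kendall_w=w,
        kendall_p=wp,
        cluster_diet_tests=pd.DataFrame(diet_rows),
        dropped_taxa=const,
    )


def guild_cluster_by_compartment(
    abs_table: AbsoluteAbundanceTable,
    records: Sequence[SampleRecord],
    top_k: int = DEFAULT_TOP_K,
    k_range: Sequence[int] = range(2, 9),
    day: int = 7,
) -> dict[str, GuildResult]:
    """Run guild clustering per intestinal compartment on the top taxa."""
    by_id = records_by_id(records)
    frame = abs_table.frame("abs_per_compartment")
    results: dict[str, GuildResult] = {}
    for comp in INTESTINAL_COMPARTMENTS:
        sids = [s for s in abs_table.sample_ids
                if by_id[s].compartment == comp and by_id[s].day == day]
        if len(sids) < 3:
            continue
        sub = frame.loc[sids]
        top = select_top_taxa(sub, top_k)
        results[comp.value] = guild_cluster(
            sub[top], records=records, compartment=comp.value, k_range=k_range
        )
    return results


def write_guilds(results: dict[str, GuildResult], path: str | Path) -> None:
    rows = []
    for comp, res in results.items():
        for taxon, cl in res.assignments.items():
            rows.append({
                "compartment": comp,
                "taxon_id": taxon,
                "cluster": cl,
                "k_selected": res.k_selected,
                "kendall_w": res.kendall_w,
                "kendall_p": res.kendall_p,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_artifact_summary(report: Sequence[L2FCRecord], path: str | Path) -> None:
    df = report_to_frame(report)
    lines = []
    for comp, sub in df.groupby("compartment"):
        n_abs = int(sub["significant_absolute"].sum())
        n_rel = int(sub["significant_relative"].sum())
        flagged = sub[sub["artifact_flag"] != ArtifactFlag.NONE.value]
        lines.append(
            f"{comp}: {n_abs} taxa significant on the absolute scale, "
            f"{n_rel} on the relative scale; "
            f"{len(flagged)} compositional-artifact flags"
        )
        for _, r in flagged.iterrows():
            lines.append(
                f"  {r.taxon_id}: {r.artifact_flag} "
                f"(l2fc_rel={r.l2fc_relative:+.2f}, l2fc_abs={r.l2fc_absolute:+.2f})"
            )
    Path(path).write_text("\n".join(lines) + "\n")
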