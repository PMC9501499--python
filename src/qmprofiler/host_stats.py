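"""Assumption-gated two-way ANOVA workflow with Bonferroni post-hoc tests.

The same testing recipe is applied to every host and microbiome
endpoint (weights, intake, alpha diversity, water content, C:N, flux,
...): residual normality is checked with Shapiro-Wilk and
homoscedasticity with Levene's test (median-centered, Brown-Forsythe
variant); when residuals are non-normal at alpha = 0.05 the response is
square-root transformed once and the model refit; a two-way ANOVA with
interaction is fit (Type II sums of squares, so balanced designs
reproduce the classical sequential decomposition); per-factor R^2 is the
factor's share of total sum of squares; significant factors trigger
pairwise Student's t-tests with Bonferroni adjustment over the number of
comparisons performed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data_model import FLOAT_FORMAT

logger = logging.getLogger("qmprofiler")

__all__ = ["AnovaWorkflowResult", "anova_workflow", "posthoc_bonferroni"]


@dataclass
class AnovaWorkflowResult:
    endpoint: str
    factor_names: tuple[str, str]
    transformation: str                  # "none" or "sqrt"
    normality_p: float                   # Shapiro-Wilk on (untransformed) residuals
    homoscedasticity_p: float            # Brown-Forsythe Levene across cells
    anova: pd.DataFrame                  # term, sum_sq, df, F, p, r_squared
    posthoc: pd.DataFrame                # factor, group_a, group_b, t, p_raw, p_bonferroni
    degenerate: bool = False             # all observations identical


def posthoc_bonferroni(
    values: np.ndarray,
    groups: np.ndarray,
    comparisons: Sequence[tuple[str, str]],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise Student's t-tests with Bonferroni adjustment.

    ``p_bonferroni = min(1, p_raw * m)`` where m is the number of
    comparisons actually performed.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    known = set(np.unique(groups))
    rows = []
    for a, b in comparisons:
        if a not in known or b not in known:
            raise ValueError(f"unknown group label in comparison ({a}, {b})")
        va, vb = values[groups == a], values[groups == b]
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"comparison ({a}, {b}): each group needs >= 2 samples")
        t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    m = len(rows)
    for r in rows:
        r["p_bonferroni"] = min(1.0, r["p_raw"] * m)
    return pd.DataFrame(rows)


def _fit_model(df: pd.DataFrame, formula: str) -> pd.DataFrame:
    model = smf.ols(formula, data=df).fit()
    # Type II SS: balanced designs match the classical decomposition,
    # unbalanced ones test each main effect adjusted for the other.
    table = sm.stats.anova_lm(model, typ=2)
    return table, model


def anova_workflow(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    endpoint: str = "endpoint",
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
    alpha: float = 0.05,
    equal_var_posthoc: bool = True,
) -> AnovaWorkflowResult:
    """Two-way ANOVA with assumption gates, sqrt fallback, and post-hocs.

    The Shapiro-Wilk test on residuals of the untransformed fit gates a
    single square-root retry (requiring non-negative data). Post-hoc
    pairwise t-tests run for each significant factor, Bonferroni-adjusted
    over the comparisons of that run.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "factor_a": np.asarray(factor_a).astype(str),
        "factor_b": np.asarray(factor_b).astype(str),
    })
    if df["value"].isna().any():
        raise ValueError("missing values in endpoint")
    multi = [c for c in ("factor_a", "factor_b") if df[c].nunique() >= 2]
    if not multi:
        raise ValueError("at least one factor needs 2 levels")
    if len(multi) == 2:
        formula = "value ~ C(factor_a) * C(factor_b)"
        cell_cols = ["factor_a", "factor_b"]
    else:
        # a factor collapsed to one level: reduce to one-way ANOVA
        logger.warning("one factor has a single level; fitting one-way ANOVA")
        formula = f"value ~ C({multi[0]})"
        cell_cols = multi
    cells = df.groupby(cell_cols)["value"]
    if (cells.count() < 2).any():
        raise ValueError("every factor-level cell needs >= 2 replicates")

    cell_values = [g.to_numpy() for _, g in cells]
    if np.ptp(df["value"].to_numpy()) == 0:
        # Zero variance everywhere: SS decomposition is all zeros, no test.
        anova = pd.DataFrame({
            "term": [factor_names[0], factor_names[1],
                     f"{factor_names[0]}:{factor_names[1]}", "residual"],
            "sum_sq": 0.0, "df": np.nan, "F": np.nan, "p": np.nan, "r_squared": np.nan,
        })
        return AnovaWorkflowResult(
            endpoint, factor_names, "none", float("nan"), float("nan"),
            anova, pd.DataFrame(), degenerate=True,
        )

    table, model = _fit_model(df, formula)
    normality_p = float(stats.shapiro(model.resid).pvalue)
    homo_p = float(stats.levene(*cell_values, center="median").pvalue)

    transformation = "none"
    if normality_p < alpha:
        if (df["value"] < 0).any():
            raise ValueError(
                "residuals non-normal but values are negative; sqrt transform "
                "impossible — add an offset or transform upstream"
            )
        df = df.assign(value=np.sqrt(df["value"]))
        table, model = _fit_model(df, formula)
        transformation = "sqrt"

    ss_total = float(table["sum_sq"].sum())
    term_map = {
        "C(factor_a)": factor_names[0],
        "C(factor_b)": factor_names[1],
        "C(factor_a):C(factor_b)": f"{factor_names[0]}:{factor_names[1]}",
        "Residual": "residual",
    }
    rows = []
    for term, row in table.iterrows():
        rows.append({
            "term": term_map.get(term, term),
            "sum_sq": float(row["sum_sq"]),
            "df": float(row["df"]),
            "F": float(row["F"]) if np.isfinite(row.get("F", np.nan)) else float("nan"),
            "p": float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else float("nan"),
            "r_squared": float(row["sum_sq"]) / ss_total if ss_total > 0 else float("nan"),
        })
    anova = pd.DataFrame(rows)

    posthoc_frames = []
    for col, name in (("factor_a", factor_names[0]), ("factor_b", factor_names[1])):
        match = anova.loc[anova["term"] == name, "p"]
        if match.empty:
            continue  # factor absent from a one-way reduction
        p = match.iloc[0]
        levels = sorted(df[col].unique())
        if np.isfinite(p) and p < alpha and len(levels) >= 2:
            comparisons = list(itertools.combinations(levels, 2))
            ph = posthoc_bonferroni(
                df["value"].to_numpy(), df[col].to_numpy(), comparisons,
                equal_var=equal_var_posthoc,
            )
            ph.insert(0, "factor", name)
            posthoc_frames.append(ph)
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(columns=["factor", "group_a", "group_b", "t", "p_raw", "p_bonferroni"])
    )
    return AnovaWorkflowResult(
        endpoint=endpoint,
        factor_names=factor_names,
        transformation=transformation,
        normality_p=normality_p,
        homoscedasticity_p=homo_p,
        anova=anova,
        posthoc=posthoc,
    )


def write_stats_report(results: Sequence[AnovaWorkflowResult], path: str | Path) -> None:
    rows = []
    for res in results:
        for _, r in res.anova.iterrows():
            rows.append({
                "endpoint": res.endpoint,
                "term": r["term"],
                "sum_sq": r["sum_sq"],
                "df": r["df"],
                "F": r["F"],
                "p": r["p"],
                "r_squared": r["r_squared"],
                "transformation": res.transformation,
                "normality_p": res.normality_p,
                "homoscedasticity_p": res.homoscedasticity_p,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
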