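"""Rarefaction, alpha diversity, Bray-Curtis ordination, and PERMANOVA.

Alpha diversity (observed richness, Shannon with natural log, and the
Gini-Simpson index 1 - sum p^2) is computed on counts rarefied to a
common depth (pipeline default 1763 reads) so richness is comparable
across libraries. Beta diversity uses Bray-Curtis dissimilarity on
unrarefied relative abundances, ordinated by principal coordinates
analysis, with group effects tested by distance-based permutational
multivariate ANOVA (PERMANOVA).

PERMANOVA here supports several factors with sequential (Type I) sums
of squares computed on the Gower-centered inner-product matrix
G = -1/2 J D^2 J (the partitioning of squared dissimilarities among and
within groups); factor order is the caller's order. p-values come from
permuting sample labels: p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .data_model import FLOAT_FORMAT

__all__ = [
    "DEFAULT_RAREFACTION_DEPTH",
    "DiversityResult",
    "OrdinationResult",
    "PermanovaResult",
    "rarefy",
    "observed",
    "shannon",
    "simpson",
    "alpha_diversity_table",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
]

#: Standard rarefaction depth of the pipeline.
DEFAULT_RAREFACTION_DEPTH = 1763


@dataclass
class DiversityResult:
    sample_id: str
    observed_richness: int
    shannon: float
    simpson: float
    rarefaction_depth: int


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    dissimilarity: np.ndarray
    coordinates: np.ndarray        # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class PermanovaResult:
    factors: list[str]
    r_squared: dict[str, float]
    pseudo_f: dict[str, float]
    p_value: dict[str, float]
    n_permutations: int


# ---------------------------------------------------------------------------
# Rarefaction and alpha diversity
# ---------------------------------------------------------------------------

def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample ``depth`` reads without replacement (multivariate hypergeometric)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(
            f"rarefaction depth {depth} exceeds library size {total}; "
            "filter shallow samples first (filter_min_reads)"
        )
    if depth == total:
        return counts.astype(np.int64).copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def _proportions(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample: cannot compute diversity")
    return counts / total


def observed(counts: np.ndarray) -> int:
    """Number of taxa with at least one read."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValueError("empty sample: cannot compute diversity")
    return int(np.count_nonzero(counts))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy -sum p ln p (natural log)."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p^2, in [0, 1]."""
    p = _proportions(counts)
    return float(1.0 - (p * p).sum())


def alpha_diversity_table(
    sample_ids: Sequence[str],
    counts: np.ndarray,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Rarefy each sample to ``depth`` and compute the three alpha metrics."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for sid, row in zip(sample_ids, np.asarray(counts)):
        r = rarefy(row, depth, rng)
        rows.append({
            "sample_id": sid,
            "observed_richness": observed(r),
            "shannon": shannon(r),
            "simpson": simpson(r),
            "rarefaction_depth": depth,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1].

    A semimetric: it can violate the triangle inequality, which is why
    ordination goes through PCoA rather than a metric embedding.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined for two all-zero samples")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(abundances: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity matrix (samples x samples)."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    n = a.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(a[i] - a[i + 1:]).sum(axis=1)
        denom = (a[i] + a[i + 1:]).sum(axis=1)
        if np.any(denom <= 0):
            raise ValueError("Bray-Curtis undefined for two all-zero samples")
        d[i, i + 1:] = d[i + 1:, i] = diff / denom
    return d


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return 0.5 * (d + d.T)


def pcoa(
    dissimilarity: np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> OrdinationResult:
    """Principal coordinates analysis (classical MDS on the Gower matrix)."""
    d = _check_dissimilarity(dissimilarity)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(d))]
    with warnings.catch_warnings():
        # Bray-Curtis is a semimetric, so mildly negative eigenvalues are
        # expected and reported in the result, not a failure mode.
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    return OrdinationResult(
        sample_ids=ids,
        dissimilarity=d,
        coordinates=res.samples.to_numpy(),
        eigenvalues=res.eigvals.to_numpy(),
        proportion_explained=res.proportion_explained.to_numpy(),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse handles rank-deficient dummy codings
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design_matrices(factors: dict[str, Sequence]) -> tuple[list[np.ndarray], list[int]]:
    """Cumulative dummy-coded design matrices, one per sequential model."""
    n = len(next(iter(factors.values())))
    blocks = [np.ones((n, 1))]
    dfs = []
    for name, labels in factors.items():
        labels = np.asarray(labels)
        levels = pd.unique(labels)
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs at least 2 groups")
        dummies = np.column_stack([(labels == lv).astype(float) for lv in levels])
        blocks.append(dummies)
        dfs.append(len(levels) - 1)
    designs = []
    for k in range(1, len(blocks)):
        designs.append(np.column_stack(blocks[: k + 1]))
    return designs, dfs


def permanova(
    dissimilarity: np.ndarray,
    factors: dict[str, Sequence] | Sequence,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> PermanovaResult:
    """Distance-based permutational multivariate ANOVA.

    ``factors`` maps factor name to per-sample labels (a bare sequence is
    treated as a single factor named "group"). Sums of squares are
    sequential in the given factor order.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not isinstance(factors, dict):
        factors = {"group": list(factors)}
    d = _check_dissimilarity(dissimilarity)
    n = len(d)
    for name, labels in factors.items():
        if len(labels) != n:
            raise ValueError(f"factor {name!r} has {len(labels)} labels for {n} samples")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")

    g = _gower_center(d)
    ss_total = float(np.trace(g))
    designs, dfs = _design_matrices(factors)
    hats = [_hat(x) for x in designs]
    df_model_full = sum(dfs)
    df_resid = n - 1 - df_model_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def factor_f(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss_seq = []
        prev = 0.0
        for h in hats:
            cur = float(np.sum(h * gmat))  # trace(H G) for symmetric H
            ss_seq.append(cur - prev)
            prev = cur
        ss_seq = np.asarray(ss_seq)
        ss_res = float(np.trace(gmat)) - prev
        with np.errstate(divide="ignore"):  # perfect separation: F = inf
            f = (ss_seq / np.asarray(dfs)) / (ss_res / df_resid)
        return ss_seq, f

    ss_obs, f_obs = factor_f(g)
    exceed = np.zeros(len(dfs))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, f_perm = factor_f(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs - 1e-12
    pvals = (exceed + 1.0) / (n_permutations + 1.0)

    names = list(factors)
    return PermanovaResult(
        factors=names,
        r_squared={k: float(ss / ss_total) for k, ss in zip(names, ss_obs)},
        pseudo_f={k: float(f) for k, f in zip(names, f_obs)},
        p_value={k: float(p) for k, p in zip(names, pvals)},
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_diversity(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_ordination(result: OrdinationResult, path: str | Path) -> None:
    n_axes = min(10, result.coordinates.shape[1])
    df = pd.DataFrame(
        result.coordinates[:, :n_axes],
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    df.insert(0, "sample_id", result.sample_ids)
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(
            FLOAT_FORMAT % v for v in result.eigenvalues[:n_axes]) + "\n")
        fh.write("# proportion_explained\t" + "\t".join(
            FLOAT_FORMAT % v for v in result.proportion_explained[:n_axes]) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_permanova(result: PermanovaResult, path: str | Path) -> None:
    pd.DataFrame([
        {
            "factor": k,
            "r_squared": result.r_squared[k],
            "pseudo_f": result.pseudo_f[k],
            "p_value": result.p_value[k],
            "n_permutations": result.n_permutations,
        }
        for k in result.factors
    ]).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
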