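"""Methylation-expression association: qRT-PCR normalisation, per-CpG
correlation and selection, hierarchical clustering, and window aggregates.

Relative expression is the 2^(-dCt) quantification of target-vs-ACTB Ct
triplicates; correlations are Pearson r between per-CpG methylation
fractions and log2 relative expression (the scale on which the generative
model is linear), pairwise-complete with a minimum of 4 samples. CpGs with
|r| strictly above the selection threshold (0.7 in the source analysis)
enter agglomerative clustering (Euclidean distance, average linkage) of
both CpGs and samples; a 2-cluster cut exposes the position-dependent
exon-1 / intron-1 split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

from .methio import RegionWindow


class InsufficientSamplesError(ValueError):
    """Fewer usable samples than the minimum for a correlation."""


class UndefinedCorrelationError(ValueError):
    """Zero variance makes Pearson r undefined."""


# ---------------------------------------------------------------------------
# qRT-PCR


@dataclass(frozen=True)
class ExpressionResult:
    value: float  # 2^(-dCt)
    delta_ct: float
    n_target: int
    n_reference: int
    incomplete: bool  # a replicate was missing and the mean used fewer values


def relative_expression(
    target_ct: Sequence[float], reference_ct: Sequence[float]
) -> ExpressionResult:
    """Relative expression from Ct triplicates: 2^-(mean(target)-mean(reference)).

    Missing (NaN) replicates are dropped with the result flagged incomplete;
    at least one finite value per channel is required.
    """
    t = np.asarray(target_ct, dtype=float)
    r = np.asarray(reference_ct, dtype=float)
    t_ok, r_ok = t[np.isfinite(t)], r[np.isfinite(r)]
    if t_ok.size == 0 or r_ok.size == 0:
        raise ValueError("a Ct channel has no finite replicate values")
    delta = float(t_ok.mean() - r_ok.mean())
    return ExpressionResult(
        value=float(2.0 ** (-delta)),
        delta_ct=delta,
        n_target=int(t_ok.size),
        n_reference=int(r_ok.size),
        incomplete=(t_ok.size < t.size or r_ok.size < r.size),
    )


EXPRESSION_CSV_COLUMNS = [
    "sample_id",
    "ct_target_1",
    "ct_target_2",
    "ct_target_3",
    "ct_ref_1",
    "ct_ref_2",
    "ct_ref_3",
]


def load_expression_csv(path: str | Path) -> pd.DataFrame:
    """Load a triplicate Ct CSV and compute relative expression per sample."""
    df = pd.read_csv(path)
    missing = set(EXPRESSION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression CSV lacks columns: {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        res = relative_expression(
            [row["ct_target_1"], row["ct_target_2"], row["ct_target_3"]],
            [row["ct_ref_1"], row["ct_ref_2"], row["ct_ref_3"]],
        )
        rows.append(
            {
                "sample_id": row["sample_id"],
                "relative_expression": res.value,
                "delta_ct": res.delta_ct,
                "incomplete": res.incomplete,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# correlation


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_cpgs(
    meth: pd.DataFrame,
    expression: pd.Series,
    threshold: float = 0.7,
    log2_expression: bool = True,
    min_n: int = 4,
) -> pd.DataFrame:
    """Per-CpG Pearson correlation of methylation with (log2) expression.

    Pairwise-complete over samples; a CpG with fewer than ``min_n`` usable
    samples or zero variance is flagged unusable and never selected.
    Selection is strict: ``selected iff |r| > threshold``.

    Returns a DataFrame with columns cpg, r, p, n, usable, selected, reason.
    """
    expr = expression.reindex(meth.index).astype(float)
    y_all = np.log2(expr.to_numpy()) if log2_expression else expr.to_numpy()
    rows = []
    for col in meth.columns:
        x = meth[col].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y_all)
        n = int(mask.sum())
        r = p = np.nan
        usable, reason = True, ""
        if n < min_n:
            usable, reason = False, "insufficient_samples"
        elif np.var(x[mask]) == 0.0 or np.var(y_all[mask]) == 0.0:
            usable, reason = False, "zero_variance"
        else:
            r, p = _pearson(x[mask], y_all[mask])
        rows.append(
            {
                "cpg": col,
                "r": r,
                "p": p,
                "n": n,
                "usable": usable,
                "selected": bool(usable and abs(r) > threshold),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def aggregate_correlation(
    meth: pd.DataFrame,
    expression: pd.Series,
    columns: Sequence[str],
    log2_expression: bool = True,
    min_n: int = 4,
) -> tuple[float, float, int]:
    """Pearson r between a region-mean methylation and (log2) expression.

    The region mean is the per-sample unweighted mean over ``columns``
    (NaN-aware). Returns (r, p, n).
    """
    cols = [c for c in columns if c in meth.columns]
    if not cols:
        raise ValueError("no requested CpG columns present in the matrix")
    region = meth[cols].mean(axis=1, skipna=True)
    expr = expression.reindex(meth.index).astype(float)
    y = np.log2(expr.to_numpy()) if log2_expression else expr.to_numpy()
    x = region.to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        raise InsufficientSamplesError(f"only {n} usable samples (< {min_n})")
    if np.var(x[mask]) == 0.0 or np.var(y[mask]) == 0.0:
        raise UndefinedCorrelationError("zero variance in region mean or expression")
    r, p = _pearson(x[mask], y[mask])
    return r, p, n


def window_columns(cpg_info: pd.DataFrame, window: RegionWindow) -> list[str]:
    """CpG column names whose panel index falls inside a window (inclusive)."""
    sel = cpg_info[
        (cpg_info["panel_index"] >= window.lo) & (cpg_info["panel_index"] <= window.hi)
    ]
    return sel["column"].tolist()


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    cpg_linkage: np.ndarray
    sample_linkage: np.ndarray
    cpg_order: list[str]  # leaf order (column names)
    sample_order: list[str]  # leaf order (sample ids)
    cpg_clusters: pd.Series  # 2-cut labels per CpG
    sample_clusters: pd.Series  # 2-cut labels per sample


def _nan_condensed(matrix: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean condensed distance matrix."""
    d = nan_euclidean_distances(matrix)
    if not np.isfinite(d[np.triu_indices_from(d, k=1)]).all():
        raise ValueError("a pair of rows shares no observed values")
    # nan_euclidean is symmetric up to fp noise; enforce exact symmetry
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def cluster(
    meth: pd.DataFrame, method: str = "average", n_clusters: int = 2
) -> ClusterResult:
    """Agglomerative clustering of CpGs (columns) and samples (rows).

    Euclidean distance, average linkage by default; missing values handled
    with pairwise-complete distances. Leaf ordering is scipy's deterministic
    ordering (ties broken by input order). Cluster labels come from an
    ``n_clusters``-cut of each dendrogram.
    """
    if meth.shape[0] < 2 or meth.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples and 2 CpGs")
    x = meth.to_numpy(dtype=float)
    sample_link = hierarchy.linkage(_nan_condensed(x), method=method)
    cpg_link = hierarchy.linkage(_nan_condensed(x.T), method=method)
    sample_order = [
        meth.index[i] for i in hierarchy.leaves_list(sample_link)
    ]
    cpg_order = [meth.columns[i] for i in hierarchy.leaves_list(cpg_link)]
    sample_cut = hierarchy.fcluster(sample_link, n_clusters, criterion="maxclust")
    cpg_cut = hierarchy.fcluster(cpg_link, n_clusters, criterion="maxclust")
    return ClusterResult(
        cpg_linkage=cpg_link,
        sample_linkage=sample_link,
        cpg_order=list(cpg_order),
        sample_order=list(sample_order),
        cpg_clusters=pd.Series(cpg_cut, index=meth.columns, name="cluster"),
        sample_clusters=pd.Series(sample_cut, index=meth.index, name="cluster"),
    )


def ordered_matrix(meth: pd.DataFrame, result: ClusterResult) -> pd.DataFrame:
    """The methylation matrix reordered by the dendrogram leaf orders."""
    return meth.loc[result.sample_order, result.cpg_order]
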