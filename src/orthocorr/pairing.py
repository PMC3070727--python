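"""Global fold-change correspondence between species.

Builds the ortholog pair table (one row per mapped human-mouse transcript
pair with both fold changes), then summarizes it: Pearson correlation with
a least-squares line, the Mahalanobis core set (the fraction of pairs
closest to the bivariate centroid), correlation-distance hierarchical
clustering of model fold-change profiles, and trademark gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from .io import OrthologMap

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Pearson r plus the least-squares line of mouse on human fold change."""

    r: float
    slope: float
    intercept: float
    n_pairs: int

    def to_dict(self) -> Dict[str, float]:
        return {
            "r": self.r,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_pairs": self.n_pairs,
        }


@dataclass
class CoreSet:
    """Pairs closest to the bivariate centroid by Mahalanobis distance."""

    member: np.ndarray  # boolean flag per pair
    fraction: float
    centroid: np.ndarray
    covariance: np.ndarray
    distances_sq: np.ndarray

    @property
    def n_core(self) -> int:
        return int(self.member.sum())


def build_pair_table(
    human: pd.DataFrame, mouse: pd.DataFrame, omap: OrthologMap
) -> pd.DataFrame:
    """One row per ortholog pair with fold changes on both sides.

    Pairs whose human or mouse transcript is absent from the respective
    DE table are dropped (counts logged).  Many-to-many pairs each
    contribute one row.
    """
    pairs = omap.pairs[["human_transcript", "mouse_transcript"]].copy()
    pairs["human_log2fc"] = human["log2fc"].reindex(pairs["human_transcript"]).to_numpy()
    pairs["mouse_log2fc"] = mouse["log2fc"].reindex(pairs["mouse_transcript"]).to_numpy()
    n_missing_h = int(pairs["human_log2fc"].isna().sum())
    n_missing_m = int(pairs["mouse_log2fc"].isna().sum())
    if n_missing_h or n_missing_m:
        logger.info(
            "build_pair_table: dropped %d pairs missing human FC, %d missing mouse FC",
            n_missing_h,
            n_missing_m,
        )
    out = pairs.dropna().reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no ortholog pairs with fold changes on both sides")
    return out


def fold_change_correlation(pair_table: pd.DataFrame) -> CorrelationResult:
    """Pearson r and least-squares regression of mouse log2fc on human log2fc."""
    x = pair_table["human_log2fc"].to_numpy(dtype=float)
    y = pair_table["mouse_log2fc"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >=3 pairs for a defined correlation")
    for name, v in (("human_log2fc", x), ("mouse_log2fc", y)):
        if np.var(v) == 0:
            raise ValueError(f"zero variance in {name}; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=len(x),
    )


def mahalanobis_core(pair_table: pd.DataFrame, fraction: float = 0.75) -> CoreSet:
    """Flag the ceil(fraction * n) pairs closest to the bivariate centroid.

    Distance is Mahalanobis with the plain sample covariance of the
    (human_log2fc, mouse_log2fc) cloud; membership is therefore invariant
    under affine maps of the cloud.
    """
    xy = pair_table[["human_log2fc", "mouse_log2fc"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 10:
        raise ValueError("need >=10 pairs for a core set")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    centroid = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("singular covariance; pair cloud is degenerate")
    delta = xy - centroid
    d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
    k = int(np.ceil(fraction * n))
    order = np.argsort(d2, kind="stable")
    member = np.zeros(n, dtype=bool)
    member[order[:k]] = True
    return CoreSet(
        member=member,
        fraction=fraction,
        centroid=centroid,
        covariance=cov,
        distances_sq=d2,
    )


def cluster_models(
    fc_profiles: pd.DataFrame, method: str = "average"
) -> Dict[str, object]:
    """Hierarchical clustering of fold-change profiles (one column per model).

    Distance between columns is 1 - Pearson r.  Returns the scipy linkage
    matrix, the column labels, and a Newick string of the dendrogram.
    """
    if fc_profiles.shape[1] < 2:
        raise ValueError("need >=2 columns (models) to cluster")
    arr = fc_profiles.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    if np.any(sds == 0):
        bad = fc_profiles.columns[sds == 0].tolist()
        raise ValueError(f"constant column(s): {bad}")
    corr = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    condensed = np.maximum(dist[iu], 0.0)
    Z = linkage(condensed, method=method)
    labels = list(fc_profiles.columns)
    return {"linkage": Z, "labels": labels, "newick": linkage_to_newick(Z, labels)}


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    body = walk(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"


def trademark_genes(
    human: pd.DataFrame,
    omap: OrthologMap,
    k: int = 50,
    direction: str = "up",
    representative: str = "lowest_p",
) -> pd.DataFrame:
    """Top-k human genes by signed fold change, restricted to genes with a mouse ortholog.

    One representative transcript per gene: the lowest-p transcript by
    default, or the largest-|log2fc| one (``representative="max_lfc"``).
    Ties at rank k are broken by smaller q, then gene symbol.  If fewer than
    k genes are eligible, all are returned with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if representative not in ("lowest_p", "max_lfc"):
        raise ValueError("representative must be 'lowest_p' or 'max_lfc'")
    table = human[human["gene"].notna()].copy()
    mapped_transcripts = set(omap.pairs["human_transcript"])
    gene_mapped = (
        table.assign(mapped=table.index.isin(mapped_transcripts))
        .groupby("gene")["mapped"]
        .any()
    )
    table = table[table["gene"].isin(gene_mapped.index[gene_mapped])]
    if len(table) == 0:
        raise ValueError("no genes with mouse orthologs")

    if representative == "lowest_p":
        idx = table.groupby("gene")["p"].idxmin()
    else:
        idx = table.assign(abs_lfc=table["log2fc"].abs()).groupby("gene")["abs_lfc"].idxmax()
    reps = table.loc[idx].copy()
    reps["transcript_id"] = reps.index

    ascending = direction == "down"
    reps = reps.sort_values(
        by=["log2fc", "q", "gene"], ascending=[ascending, True, True], kind="stable"
    )
    if len(reps) < k:
        logger.warning("only %d eligible genes for k=%d trademark list", len(reps), k)
    return reps.head(k).set_index("gene")[["transcript_id", "log2fc", "stat", "p", "q"]]
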