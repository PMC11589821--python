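"""Co-expression networks around hotspot targets and single query genes.

A CEN (co-expression network) takes a hotspot's target genes plus candidate
transcription factors, computes all pairwise Pearson correlation
coefficients over lines, and clusters genes by average-linkage hierarchical
clustering on 1 - PCC, cutting the dendrogram at the largest merge-height
gap (or a fixed k).  A TWCEN (transcriptome-wide CEN) thresholds a single
query gene's correlation against every other expressed gene at >= 0.85
(positive network) and <= -0.85 (negative network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["CoexpressionNetwork", "build_cen", "build_twcen", "mean_pcc"]

POS_THRESHOLD = 0.85
NEG_THRESHOLD = -0.85


@dataclass
class CoexpressionNetwork:
    """Pairwise-PCC network over a gene set with cluster labels."""

    members: list[str]
    pcc: pd.DataFrame = field(repr=False)
    clusters: dict[str, str]  # gene -> "C1", "C2", ... by descending size
    kind: str = "CEN"

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))

    def cluster_members(self, label: str) -> list[str]:
        return [g for g, c in self.clusters.items() if c == label]


def _drop_constant(expression: pd.DataFrame, genes: list[str]) -> list[str]:
    sub = expression.loc[genes]
    sd = sub.to_numpy(dtype=float).std(axis=1)
    constant = [g for g, s in zip(genes, sd) if s == 0]
    if constant:
        warnings.warn(
            f"{len(constant)} constant-expression gene(s) dropped (PCC undefined): "
            f"{constant[:5]}",
            stacklevel=3,
        )
    return [g for g, s in zip(genes, sd) if s > 0]


def build_cen(
    gene_set: list[str],
    candidate_tfs: list[str],
    expression: pd.DataFrame,
    n_clusters: int | None = None,
) -> CoexpressionNetwork:
    """Build the CEN over a hotspot's targets plus candidate TFs.

    ``expression`` is genes x lines (normalized).  Cluster count defaults to
    the largest merge-height gap of the average-linkage dendrogram; pass
    ``n_clusters`` to fix it.  Cluster labels C1, C2, ... are ordered by
    descending size.
    """
    members = list(dict.fromkeys([*gene_set, *candidate_tfs]))
    missing = [g for g in members if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    members = _drop_constant(expression, members)
    if len(members) < 3:
        raise ValueError("a co-expression network needs >= 3 non-constant genes")

    x = expression.loc[members].to_numpy(dtype=float)
    pcc = np.corrcoef(x)
    np.fill_diagonal(pcc, 1.0)
    dist = 1.0 - pcc
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(np.maximum(dist, 0.0), checks=False), method="average")

    if n_clusters is None:
        heights = z[:, 2]
        if len(heights) >= 2:
            gaps = np.diff(heights)
            cut_at = int(np.argmax(gaps))
            n_clusters = len(members) - cut_at - 1
        else:
            n_clusters = 1
    labels = fcluster(z, t=n_clusters, criterion="maxclust")

    # relabel by descending cluster size (ties: first appearance)
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], list(labels).index(c)))
    rename = {c: f"C{i + 1}" for i, c in enumerate(order)}
    clusters = {g: rename[c] for g, c in zip(members, labels)}

    return CoexpressionNetwork(
        members=members,
        pcc=pd.DataFrame(pcc, index=members, columns=members),
        clusters=clusters,
        kind="CEN",
    )


def _pcc_to_query(query: np.ndarray, others: np.ndarray) -> np.ndarray:
    qc = query - query.mean()
    oc = others - others.mean(axis=1, keepdims=True)
    denom = np.sqrt((oc**2).sum(axis=1)) * np.sqrt((qc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        return (oc @ qc) / np.where(denom > 0, denom, np.nan)


def build_twcen(
    query_gene: str,
    expression: pd.DataFrame,
    pos_threshold: float = POS_THRESHOLD,
    neg_threshold: float = NEG_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positive and negative transcriptome-wide networks for one gene.

    Returns (pos, neg) frames with columns gene_id, pcc: genes (query
    excluded) whose PCC with the query is >= pos_threshold, resp.
    <= neg_threshold; boundary values are included.  Constant genes are
    dropped with a warning.
    """
    if query_gene not in expression.index:
        raise KeyError(f"query gene {query_gene!r} not in expression matrix")
    q = expression.loc[query_gene].to_numpy(dtype=float)
    if q.std() == 0:
        raise ValueError(f"query gene {query_gene!r} has constant expression")
    others = expression.drop(index=query_gene)
    r = _pcc_to_query(q, others.to_numpy(dtype=float))
    n_const = int(np.isnan(r).sum())
    if n_const:
        warnings.warn(f"{n_const} constant-expression gene(s) dropped (PCC undefined)",
                      stacklevel=2)
    frame = pd.DataFrame({"gene_id": others.index, "pcc": r}).dropna()
    pos = frame[frame["pcc"] >= pos_threshold].sort_values("pcc", ascending=False)
    neg = frame[frame["pcc"] <= neg_threshold].sort_values("pcc")
    return pos.reset_index(drop=True), neg.reset_index(drop=True)


def mean_pcc(expression: pd.DataFrame, query_gene: str, gene_list: list[str]) -> float:
    """Mean PCC between a query gene and a list of genes (e.g. the homologs
    summarized in a network figure caption)."""
    q = expression.loc[query_gene].to_numpy(dtype=float)
    others = expression.loc[gene_list].to_numpy(dtype=float)
    return float(np.nanmean(_pcc_to_query(q, others)))
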