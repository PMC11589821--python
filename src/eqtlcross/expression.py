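"""Expression filtering, normalization, and the parental DE screen.

Raw counts are filtered by the "expressed" rule (count >= 2 in at least 25%
of lines by default), normalized by the DESeq2-style median-of-ratios size
factors, and the two parental groups are compared with a Welch t-test on
log2(normalized+1) gated by fold-change and BH-adjusted p-value — a
deliberate lightweight stand-in for a full negative-binomial Wald test that
preserves the FC/FDR gating the downstream annotation consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_expressed",
    "median_of_ratios_normalize",
    "parental_de",
    "DegRecord",
]


def filter_expressed(
    counts: pd.DataFrame, min_count: int = 2, min_fraction: float = 0.25
) -> pd.Index:
    """Genes considered expressed: count >= min_count in at least
    ceil(min_fraction * n_lines) lines (boundary inclusive).

    ``counts`` is genes x lines, raw integers.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    need = math.ceil(min_fraction * counts.shape[1])
    ok = (counts.to_numpy() >= min_count).sum(axis=1) >= need
    return counts.index[ok]


def median_of_ratios_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors and the normalized matrix.

    Per line: the median, over genes with nonzero counts in every line, of
    count / geometric-mean(count across lines); normalized value is
    count / size factor.  Requires >= 2 lines and >= 1 all-nonzero gene.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization needs at least two lines")
    x = counts.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every line; filter genes or check "
            "that the matrix is genes x lines"
        )
    ref = x[all_nonzero]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    log_size = np.median(np.log(ref) - log_geo, axis=0)
    # rescale to geometric mean 1: downstream statistics are scale-invariant
    # and renormalizing already-normalized data then yields unit factors
    size = np.exp(log_size - log_size.mean())
    factors = pd.Series(size, index=counts.columns, name="size_factor")
    return counts / factors, factors


@dataclass(frozen=True)
class DegRecord:
    """One differential-expression call between parental groups."""

    gene_id: str
    fold_change: float  # linear scale, direction relative to group A (reference)
    p_adjusted: float
    direction: str  # "up" (higher in B than reference A) or "down"
    is_deg: bool


def parental_de(
    counts_group_a: pd.DataFrame,
    counts_group_b: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
) -> list[DegRecord]:
    """Two-group DE screen between parental replicate sets.

    Group A is the reference (the early-maturing parent in the motivating
    design).  Per gene: Welch t-test on log2(normalized+1); BH adjustment
    across all tested genes; a gene is a DEG iff adjusted p <= ``fdr`` AND
    linear fold change >= ``fc_threshold`` in either direction.  A gene with
    fold change just under the gate is not a DEG no matter how small its
    p-value.
    """
    if counts_group_a.shape[1] < 2 or counts_group_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    genes = counts_group_a.index
    if not genes.equals(counts_group_b.index):
        raise ValueError("groups must share the same gene index")

    merged = pd.concat([counts_group_a, counts_group_b], axis=1)
    normalized, _ = median_of_ratios_normalize(merged)
    la = np.log2(normalized.iloc[:, : counts_group_a.shape[1]].to_numpy() + 1.0)
    lb = np.log2(normalized.iloc[:, counts_group_a.shape[1] :].to_numpy() + 1.0)

    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")

    mean_a = np.expm1(np.log(2) * la.mean(axis=1)) + 1e-300
    mean_b = np.expm1(np.log(2) * lb.mean(axis=1)) + 1e-300
    ratio = mean_b / mean_a
    fold = np.maximum(ratio, 1.0 / ratio)  # linear FC >= 1 in either direction

    records = []
    for i, gene in enumerate(genes):
        records.append(
            DegRecord(
                gene_id=str(gene),
                fold_change=float(fold[i]),
                p_adjusted=float(p_adj[i]),
                direction="up" if ratio[i] >= 1.0 else "down",
                is_deg=bool(p_adj[i] <= fdr and fold[i] >= fc_threshold),
            )
        )
    return records
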