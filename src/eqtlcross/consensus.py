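"""Cis/trans classification and the >= 2-method consensus merge.

An interaction is cis when its region lies on the target gene's chromosome
within 1 Mbp of the transcription start site, trans otherwise.  Interactions
from different scan methods co-validate when, for the same gene and class,
their regions padded by 500 kb on each side intersect (equivalent to an
edge-to-edge distance of at most 1 Mbp).  Co-validated interactions are
union-merged into consensus regions; a region found by the same pair in more
than one pairwise comparison is collapsed to a single record; and any trans
consensus region whose padded interval overlaps a cis region of the same
gene is de facto reclassified as cis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .scan import EqtlInteraction

__all__ = [
    "ConsensusRegion",
    "classify_cis_trans",
    "classify_all",
    "expand_region",
    "merge_methods",
    "codify",
    "parse_codification",
]

METHODS = ("ICIM", "IM", "GCIM")
CIS_WINDOW_BP = 1_000_000
PAD_BP = 500_000


@dataclass
class ConsensusRegion:
    """A merged >= 2-method eQTL region for one gene."""

    gene_id: str
    chrom: str
    start_bp: int  # union of contributing original (un-padded) regions
    end_bp: int
    methods: frozenset[str]
    members: list[EqtlInteraction] = field(repr=False)
    regulation: str = "trans"  # final class after the de-facto rule

    @property
    def best_lod(self) -> float:
        return max(m.lod for m in self.members)


def classify_cis_trans(
    interaction: EqtlInteraction,
    gene_annotation: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
) -> str:
    """cis iff the region is on the gene's chromosome and the distance from
    the TSS to the [start, end] interval is <= window_bp (0 when the TSS
    falls inside; the boundary at exactly window_bp is cis)."""
    ann = gene_annotation.set_index("gene_id") if gene_annotation.index.name != "gene_id" \
        else gene_annotation
    if interaction.gene_id not in ann.index:
        raise KeyError(f"gene {interaction.gene_id!r} has no annotation record")
    row = ann.loc[interaction.gene_id]
    if str(row["chrom"]) != interaction.chrom:
        return "trans"
    tss = int(row["tss_bp"])
    if interaction.left_bp <= tss <= interaction.right_bp:
        dist = 0
    else:
        dist = min(abs(tss - interaction.left_bp), abs(tss - interaction.right_bp))
    return "cis" if dist <= window_bp else "trans"


def classify_all(
    interactions: list[EqtlInteraction],
    gene_annotation: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
) -> list[EqtlInteraction]:
    """Set ``regulation`` on every interaction in place; returns the list."""
    ann = gene_annotation.set_index("gene_id") if gene_annotation.index.name != "gene_id" \
        else gene_annotation
    for it in interactions:
        it.regulation = classify_cis_trans(it, ann, window_bp)
    return interactions


def expand_region(
    start_bp: int, end_bp: int, pad_bp: int = PAD_BP, chrom_length: int | None = None
) -> tuple[int, int]:
    """Pad a region by ``pad_bp`` on each side, clamped to [1, chrom_length]."""
    lo = max(1, start_bp - pad_bp)
    hi = end_bp + pad_bp
    if chrom_length is not None:
        hi = min(chrom_length, hi)
    return lo, hi


def _padded_overlap(a: EqtlInteraction, b: EqtlInteraction, pad_bp: int) -> bool:
    if a.chrom != b.chrom:
        return False
    a_lo, a_hi = expand_region(a.left_bp, a.right_bp, pad_bp)
    b_lo, b_hi = expand_region(b.left_bp, b.right_bp, pad_bp)
    return a_lo <= b_hi and b_lo <= a_hi


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_methods(
    interactions_by_method: dict[str, list[EqtlInteraction]],
    pad_bp: int = PAD_BP,
) -> list[ConsensusRegion]:
    """Retain signals found by >= 2 methods within 1 Mbp of each other.

    Interactions must already carry a cis/trans ``regulation`` label (see
    :func:`classify_all`).  For each gene and class separately, the three
    pairwise comparisons (ICIM vs IM and ICIM vs GCIM with ICIM as reference;
    IM vs GCIM with IM as reference) co-validate two interactions when they
    share the chromosome and their +/- pad_bp expanded intervals intersect.
    Co-validated interactions are union-merged; a pair recovered by more than
    one comparison collapses into one consensus record.  Finally every trans
    consensus region whose padded interval intersects a cis region of the
    same gene is reclassified cis.
    """
    supplied = [m for m, lst in interactions_by_method.items() if lst is not None]
    if len(supplied) < 2:
        raise ValueError("consensus merging needs interactions from >= 2 methods")
    unknown = set(supplied) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    pool: list[EqtlInteraction] = []
    for method in METHODS:
        for it in interactions_by_method.get(method, []) or []:
            if it.method != method:
                raise ValueError(
                    f"interaction {it.gene_id} labelled {it.method} listed under {method}"
                )
            if it.regulation not in ("cis", "trans"):
                raise ValueError(
                    f"interaction {it.gene_id}/{it.method} lacks a cis/trans label; "
                    "run classify_all first"
                )
            pool.append(it)

    # group by (gene, class); union co-validated pairs across method pairs
    by_key: dict[tuple[str, str], list[int]] = {}
    for idx, it in enumerate(pool):
        by_key.setdefault((it.gene_id, it.regulation), []).append(idx)

    uf = _UnionFind(len(pool))
    for idxs in by_key.values():
        for ia, ib in combinations(idxs, 2):
            a, b = pool[ia], pool[ib]
            if a.method == b.method:
                continue
            if _padded_overlap(a, b, pad_bp):
                uf.union(ia, ib)

    components: dict[int, list[int]] = {}
    for idx in range(len(pool)):
        components.setdefault(uf.find(idx), []).append(idx)

    regions: list[ConsensusRegion] = []
    for idxs in components.values():
        members = [pool[i] for i in idxs]
        methods = frozenset(m.method for m in members)
        if len(methods) < 2:
            continue
        regions.append(
            ConsensusRegion(
                gene_id=members[0].gene_id,
                chrom=members[0].chrom,
                start_bp=min(m.left_bp for m in members),
                end_bp=max(m.right_bp for m in members),
                methods=methods,
                members=sorted(members, key=lambda m: (m.method, m.left_bp)),
                regulation=members[0].regulation,
            )
        )

    # trans regions overlapping a cis region of the same gene become cis
    cis_by_gene: dict[str, list[ConsensusRegion]] = {}
    for r in regions:
        if r.regulation == "cis":
            cis_by_gene.setdefault(r.gene_id, []).append(r)
    for r in regions:
        if r.regulation != "trans":
            continue
        lo, hi = expand_region(r.start_bp, r.end_bp, pad_bp)
        for c in cis_by_gene.get(r.gene_id, []):
            if c.chrom == r.chrom:
                c_lo, c_hi = expand_region(c.start_bp, c.end_bp, pad_bp)
                if lo <= c_hi and c_lo <= hi:
                    r.regulation = "cis"
                    break

    regions.sort(key=lambda r: (r.gene_id, r.chrom, r.start_bp, r.end_bp))
    return regions


def codify(regulation: str, gene_id: str, chrom: str, start_bp: int, end_bp: int) -> str:
    """Codification string, e.g. ``trans_Glyma.01G123600_GM05 40000 200000``."""
    return f"{regulation}_{gene_id}_{chrom} {start_bp} {end_bp}"


def parse_codification(text: str) -> tuple[str, str, str, int, int]:
    """Inverse of :func:`codify`."""
    head, start, end = text.rsplit(" ", 2)
    regulation, rest = head.split("_", 1)
    gene_id, chrom = rest.rsplit("_", 1)
    if regulation not in ("cis", "trans"):
        raise ValueError(f"bad codification string: {text!r}")
    return regulation, gene_id, chrom, int(start), int(end)


def consensus_frame(regions: list[ConsensusRegion]) -> pd.DataFrame:
    """Tabular view of consensus regions (one row per region)."""
    rows = []
    for r in regions:
        best = max(r.members, key=lambda m: m.lod)
        rows.append(
            {
                "gene_id": r.gene_id,
                "regulation": r.regulation,
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "methods": ",".join(sorted(r.methods)),
                "n_methods": len(r.methods),
                "best_lod": best.lod,
                "best_pve": best.pve,
                "additive": best.additive,
                "dominance": best.dominance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "regulation", "chrom", "start_bp", "end_bp",
                 "methods", "n_methods", "best_lod", "best_pve", "additive",
                 "dominance"],
    )
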