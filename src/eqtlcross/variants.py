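"""Candidate-SNP prioritization for candidate transcription factors.

Variants in listed TF genes are retained when their predicted consequence is
MODERATE or HIGH, or they sit in the 3'/5' UTR; missense variants carry a
SIFT verdict (score < 0.05 deleterious, >= 0.05 tolerated); and only
variants whose alternate allele is fixed in exactly one parental line
survive — the other parent may match the reference or be heterozygous
(heterozygous calls are flagged and shown as '*'), but never homozygous for
the alternate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantCandidate",
    "sift_verdict",
    "filter_candidates",
    "summarize_candidates",
    "merge_variant_tables",
    "write_vcf",
    "read_vcf",
]

SIFT_DELETERIOUS_BELOW = 0.05
KEEP_CONSEQUENCES = {"MODERATE", "HIGH"}
KEEP_REGIONS = {"3'UTR", "5'UTR"}


def sift_verdict(score: float | None) -> str:
    """deleterious iff score < 0.05; tolerated iff >= 0.05; N/A if absent."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "N/A"
    return "deleterious" if score < SIFT_DELETERIOUS_BELOW else "tolerated"


@dataclass(frozen=True)
class VariantCandidate:
    """One retained variant with its annotations and parental alleles."""

    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str  # HIGH | MODERATE | LOW | MODIFIER
    region: str  # CDS | 3'UTR | 5'UTR | other
    sift_score: float | None
    sift: str  # deleterious | tolerated | N/A
    parent1: str  # allele string; heterozygote as "X/Y"
    parent2: str
    parent1_het: bool
    parent2_het: bool

    @property
    def position(self) -> str:
        return f"{self.chrom}:{self.pos:,}"


def _alleles(call: str) -> set[str]:
    return set(str(call).split("/"))


def merge_variant_tables(vcf: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Join a VCF-shaped table (chrom,pos,id,ref,alt) with its companion
    annotation table on the variant id."""
    return vcf.merge(annotation, left_on="id", right_on="variant_id", how="inner")


def filter_candidates(
    variants: pd.DataFrame, tf_gene_list: list[str]
) -> list[VariantCandidate]:
    """Apply the candidate-SNP cascade.

    ``variants`` columns: chrom, pos, ref, alt, gene_id, consequence, region,
    sift_score, parent1, parent2.  Keeps variants of listed TF genes with
    (consequence in {MODERATE, HIGH}) OR (region in {3'UTR, 5'UTR}), then
    keeps only those whose alternate allele is fixed in exactly one parental
    line.  Variants in unlisted genes are silently excluded; variants lacking
    a parental genotype are dropped with a warning.  The filter is idempotent
    and order-independent.
    """
    tf_set = set(tf_gene_list)
    out: list[VariantCandidate] = []
    for row in variants.itertuples(index=False):
        if row.gene_id not in tf_set:
            continue
        consequence = str(row.consequence).upper()
        region = str(row.region)
        if consequence not in KEEP_CONSEQUENCES and region not in KEEP_REGIONS:
            continue
        p1, p2 = row.parent1, row.parent2
        if pd.isna(p1) or pd.isna(p2) or str(p1) == "" or str(p2) == "":
            warnings.warn(
                f"variant {row.chrom}:{row.pos} in {row.gene_id} dropped: "
                "missing parental genotype",
                stacklevel=2,
            )
            continue
        p1, p2 = str(p1), str(p2)
        alt, ref = str(row.alt), str(row.ref)
        # the alternate allele must be fixed in exactly one parental line; the
        # other parent may be reference or heterozygous (flagged), never
        # homozygous for the alternate
        hom_alt = [_alleles(p1) == {alt}, _alleles(p2) == {alt}]
        if hom_alt[0] == hom_alt[1]:
            continue
        score = getattr(row, "sift_score", None)
        score = None if score is None or pd.isna(score) else float(score)
        out.append(
            VariantCandidate(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                consequence=consequence,
                region=region,
                sift_score=score,
                sift=sift_verdict(score),
                parent1=p1,
                parent2=p2,
                parent1_het=len(_alleles(p1)) > 1,
                parent2_het=len(_alleles(p2)) > 1,
            )
        )
    return out


def _parent_display(call: str, het: bool) -> str:
    # heterozygote genotypes are shown as '*' in the summary table
    return "*" if het else call


def _consequence_display(c: VariantCandidate) -> str:
    if c.consequence == "MODERATE" and c.region == "CDS":
        return f"Missense ({c.sift.capitalize()})" if c.sift != "N/A" else "Missense"
    return "N/A"


def summarize_candidates(
    candidates: list[VariantCandidate],
    regions,
    gene_annotation: pd.DataFrame,
    window_bp: int = 300_000,
) -> pd.DataFrame:
    """Per-region candidate-variant table.

    ``regions`` is a list of objects with name/chrom/left_bp/right_bp
    attributes (hotspots) or (name, chrom, start, end) tuples.  A candidate
    is assigned to every region on its gene's chromosome whose interval lies
    within ``window_bp`` of the gene's TSS (the proximity window admits TFs
    just outside a hotspot).
    """
    cols = ["region", "gene_id", "snp", "ref_allele", "alt_allele",
            "genotypes", "location", "sift_consequence"]
    if not candidates:
        return pd.DataFrame(columns=cols)
    ann = gene_annotation.set_index("gene_id")

    def as_tuple(r):
        if isinstance(r, tuple):
            return r
        return (r.name, r.chrom, r.left_bp, r.right_bp)

    rows = []
    for c in candidates:
        if c.gene_id not in ann.index:
            continue
        tss = int(ann.loc[c.gene_id, "tss_bp"])
        gchrom = str(ann.loc[c.gene_id, "chrom"])
        for r in regions:
            name, chrom, start, end = as_tuple(r)
            if chrom != gchrom:
                continue
            dist = 0 if start <= tss <= end else min(abs(tss - start), abs(tss - end))
            if dist > window_bp:
                continue
            rows.append(
                {
                    "region": name,
                    "gene_id": c.gene_id,
                    "snp": c.position,
                    "ref_allele": c.ref,
                    "alt_allele": c.alt,
                    "genotypes": "/".join(
                        [c.ref,
                         _parent_display(c.parent1, c.parent1_het),
                         _parent_display(c.parent2, c.parent2_het)]
                    ),
                    "location": c.region,
                    "sift_consequence": _consequence_display(c),
                }
            )
    return pd.DataFrame(rows, columns=cols)


# ----------------------------------------------------------------------
# plain-text VCF I/O


def write_vcf(frame: pd.DataFrame, path) -> None:
    """Write a minimal uncompressed VCF 4.2 (chrom, pos, id, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=eqtlcross\n')
        for chrom in pd.unique(frame["chrom"]) if len(frame) else []:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a chrom/pos/id/ref/alt frame (cyvcf2-backed)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        rows.append((v.CHROM, v.POS, v.ID, v.REF, v.ALT[0] if v.ALT else "."))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
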