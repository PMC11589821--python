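"""End-to-end orchestration: simulate -> map -> scan -> consensus -> hotspots
-> networks -> enrichment -> variants.

``run_pipeline`` executes the stages in order on a synthetic cross, writes
each stage's table under the run directory, and emits a machine-readable
summary whose counts mirror the per-method interaction table (interactions
per method, regions with and without duplicates) and the hotspot table.
All randomness flows from one root seed via named substreams per stage, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cns
from . import hotspots as hs
from .coexpression import build_cen, build_twcen
from .enrichment import enrichment_frame, fisher_enrichment
from .expression import filter_expressed, median_of_ratios_normalize
from .genmap import build_map
from .scan import (
    ScanGrid,
    gcim_scan,
    icim_scan,
    permutation_threshold,
    scan_genes_im,
)
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genotypes,
    simulate_variants,
)
from .variants import filter_candidates, merge_variant_tables, summarize_candidates

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "interactions_for_gene"]

# LOD cutoffs used when a method's threshold is not permutation-derived:
# the GCIM stand-in keeps the population-specific defaults (7.5 for F2,
# 4.0 for RIL) of the study design it emulates.
GCIM_DEFAULT_LOD = {"F2": 7.5, "RIL": 4.0}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple[str, ...] = ("ICIM", "IM", "GCIM")
    step_cM: float = 1.0
    # per-method LOD threshold, or the string "permutation"
    thresholds: dict = field(default_factory=lambda: {"ICIM": "permutation",
                                                      "IM": "permutation"})
    gcim_model: str = "auto"  # fixed_REML for F2, fixed for RIL
    n_sample_genes: int = 100
    n_perm: int = 1000
    alpha: float = 0.05
    split_gap_cM: float = 30.0
    min_count: int = 2
    min_fraction: float = 0.25
    pad_bp: int = 500_000
    cis_window_bp: int = 1_000_000
    count_pct_minor: float = 95.0
    count_pct_major: float = 99.0
    density_pct: float = 80.0
    pos_pcc: float = 0.85
    neg_pcc: float = -0.85
    tf_window_bp: int = 300_000
    seed: int = 0

    @property
    def population(self) -> str:
        return self.simulation.population_type

    def threshold_for(self, method: str, permutation_results: dict) -> float:
        t = self.thresholds.get(method)
        if t == "permutation":
            return permutation_results[method].threshold
        if t is None:
            if method == "GCIM":
                return GCIM_DEFAULT_LOD[self.population]
            raise ValueError(f"no threshold configured for {method}")
        return float(t)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the summary dict."""

    config: PipelineConfig
    genotypes: object
    markers: pd.DataFrame
    gmap: object
    counts: pd.DataFrame
    normalized: pd.DataFrame
    truth: object
    interactions_by_method: dict
    thresholds: dict
    consensus: list
    hotspots: list
    merged_hotspots: list
    summary: dict
    out_dir: Path | None = None


def _substream_seed(root: int, label: int) -> int:
    return int(np.random.SeedSequence((root, label)).generate_state(1)[0] % (2**31))


def _pairwise_counts(by_method: dict, pad_bp: int) -> dict:
    """Table-1-style bookkeeping: consensus regions per pairwise comparison
    ("with duplicates") split by class."""
    pairs = [("ICIM", "IM"), ("ICIM", "GCIM"), ("IM", "GCIM")]
    out = {}
    for a, b in pairs:
        if a not in by_method or b not in by_method:
            continue
        regs = cns.merge_methods({a: by_method[a], b: by_method[b]}, pad_bp=pad_bp)
        out[f"{a}_vs_{b}"] = {
            "trans": sum(r.regulation == "trans" for r in regs),
            "cis": sum(r.regulation == "cis" for r in regs),
        }
    return out


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run all stages in order; artifacts land under ``out_dir`` if given."""
    stage = "simulate"
    try:
        genotypes, markers = simulate_genotypes(config.simulation)
        counts, gene_ann, truth = simulate_expression(genotypes, markers, config.simulation)

        stage = "map"
        gmap = build_map(genotypes, markers, split_gap_cM=config.split_gap_cM)

        stage = "expression"
        kept = filter_expressed(counts, config.min_count, config.min_fraction)
        normalized, size_factors = median_of_ratios_normalize(counts.loc[kept])

        stage = "threshold"
        grid = ScanGrid(gmap, genotypes, config.step_cM)
        permutation_results = {}
        for method in config.methods:
            if config.thresholds.get(method) == "permutation":
                permutation_results[method] = permutation_threshold(
                    normalized, gmap, genotypes, method=method,
                    n_sample_genes=min(config.n_sample_genes, len(normalized)),
                    n_perm=config.n_perm, alpha=config.alpha,
                    seed=_substream_seed(config.seed, 10), grid=grid,
                )
        thresholds = {
            m: config.threshold_for(m, permutation_results) for m in config.methods
        }

        stage = "scan"
        by_method: dict[str, list] = {}
        if "IM" in config.methods:
            by_method["IM"] = scan_genes_im(
                normalized, gmap, genotypes, config.step_cM,
                lod_threshold=thresholds["IM"], grid=grid,
            )
        gcim_model = config.gcim_model
        if gcim_model == "auto":
            gcim_model = "fixed_REML" if config.population == "F2" else "fixed"
        if "ICIM" in config.methods or "GCIM" in config.methods:
            from .scan import _kinship_eig, _marker_design  # shared precomputations

            C = _marker_design(genotypes)
            kin = _kinship_eig(genotypes) if (
                "GCIM" in config.methods and gcim_model == "fixed_REML"
            ) else None
            icim_list, gcim_list = [], []
            Y = normalized[genotypes.line_ids]
            for gene in normalized.index:
                y = Y.loc[gene].to_numpy(dtype=float)
                if "ICIM" in config.methods:
                    _, peaks = icim_scan(
                        y, gmap, genotypes, config.step_cM,
                        lod_threshold=thresholds["ICIM"], gene_id=str(gene),
                        grid=grid, marker_design=C,
                    )
                    icim_list.extend(peaks)
                if "GCIM" in config.methods:
                    gcim_list.extend(
                        gcim_scan(
                            y, gmap, genotypes, model=gcim_model,
                            step_cM=config.step_cM,
                            lod_threshold=thresholds["GCIM"], gene_id=str(gene),
                            grid=grid, kinship_eig=kin, marker_design=C,
                        )
                    )
            if "ICIM" in config.methods:
                by_method["ICIM"] = icim_list
            if "GCIM" in config.methods:
                by_method["GCIM"] = gcim_list

        stage = "consensus"
        for lst in by_method.values():
            cns.classify_all(lst, gene_ann, config.cis_window_bp)
        consensus = cns.merge_methods(by_method, pad_bp=config.pad_bp)
        pairwise = _pairwise_counts(by_method, config.pad_bp)

        stage = "hotspots"
        trans_regions = [r for r in consensus if r.regulation == "trans"]
        pair_counts = hs.count_by_marker_pair(trans_regions)
        if len(pair_counts) >= 2:
            hotspot_list = hs.classify_hotspots(
                pair_counts, config.population,
                config.count_pct_minor, config.count_pct_major, config.density_pct,
            )
        else:
            hotspot_list = []
        merged = hs.merge_adjacent(hotspot_list)

        stage = "networks"
        cen = None
        real_hotspots = [h for h in merged if h.hotspot_class != "none"]
        if real_hotspots:
            top = max(real_hotspots, key=lambda h: h.n_trans)
            targets = sorted(
                {
                    r.gene_id
                    for r in trans_regions
                    if r.chrom == top.chrom
                    and r.start_bp >= top.left_bp
                    and r.end_bp <= top.right_bp
                }
            )
            targets = [g for g in targets if g in normalized.index]
            if len(targets) >= 3:
                cen = build_cen(targets, [], normalized)

        stage = "enrichment"
        enrich = []
        if cen is not None:
            rng = np.random.default_rng(_substream_seed(config.seed, 20))
            terms = [f"TERM:{i:03d}" for i in range(50)]
            ann_rows = []
            for gene in normalized.index:
                for t in rng.choice(terms, size=rng.integers(0, 3), replace=False):
                    ann_rows.append((gene, t, f"synthetic process {t[-3:]}"))
            term_ann = pd.DataFrame(ann_rows, columns=["gene_id", "term_id", "term_name"])
            enrich = fisher_enrichment(
                cen.members, list(normalized.index), term_ann
            )

        stage = "variants"
        variant_summary = pd.DataFrame()
        if real_hotspots:
            top = max(real_hotspots, key=lambda h: h.n_trans)
            near = gene_ann[
                (gene_ann["chrom"] == top.chrom)
                & (gene_ann["tss_bp"] >= top.left_bp - config.tf_window_bp)
                & (gene_ann["tss_bp"] <= top.right_bp + config.tf_window_bp)
            ]["gene_id"].tolist()
            if near:
                tables = simulate_variants(config.simulation, near, gene_ann)
                merged_variants = merge_variant_tables(tables.vcf, tables.annotation)
                candidates = filter_candidates(merged_variants, near)
                variant_summary = summarize_candidates(
                    candidates, real_hotspots, gene_ann, config.tf_window_bp
                )

        stage = "summary"
        summary = {
            "population": config.population,
            "seed": config.seed,
            "thresholds": {m: round(float(t), 6) for m, t in thresholds.items()},
            "n_lines": genotypes.n_lines,
            "n_markers": genotypes.n_markers,
            "n_linkage_groups": len(gmap),
            "n_genes_simulated": config.simulation.n_genes,
            "n_genes_expressed": int(len(kept)),
            "interactions_per_method": {
                m: {
                    "trans": sum(i.regulation == "trans" for i in lst),
                    "cis": sum(i.regulation == "cis" for i in lst),
                }
                for m, lst in by_method.items()
            },
            "pairwise_regions_with_duplicates": pairwise,
            "consensus_regions_unique": {
                "trans": sum(r.regulation == "trans" for r in consensus),
                "cis": sum(r.regulation == "cis" for r in consensus),
            },
            "hotspots": [
                {
                    "name": h.name,
                    "class": h.hotspot_class,
                    "n_trans": h.n_trans,
                    "size_bp": h.size_bp,
                }
                for h in merged
                if h.hotspot_class != "none"
            ],
            "n_variant_candidates": int(len(variant_summary)),
        }
    except Exception as err:  # pragma: no cover - error path exercised in tests
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        config=config, genotypes=genotypes, markers=markers, gmap=gmap,
        counts=counts, normalized=normalized, truth=truth,
        interactions_by_method=by_method, thresholds=thresholds,
        consensus=consensus, hotspots=hotspot_list, merged_hotspots=merged,
        summary=summary,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genotypes.write_tsv(out / "genotypes.tsv")
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        gmap.write_tsv(out / "map.tsv")
        counts.to_csv(out / "counts.tsv", sep="\t")
        normalized.to_csv(out / "normalized.tsv", sep="\t")
        size_factors.to_csv(out / "size_factors.tsv", sep="\t")
        gene_ann.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
        truth.to_json(out / "ground_truth.json")
        for m, lst in by_method.items():
            interactions_frame(lst).to_csv(out / f"peaks_{m.lower()}.tsv",
                                           sep="\t", index=False)
        cns.consensus_frame(consensus).to_csv(out / "consensus.tsv", sep="\t", index=False)
        with open(out / "codifications.txt", "w") as fh:
            for r in consensus:
                fh.write(cns.codify(r.regulation, r.gene_id, r.chrom,
                                    r.start_bp, r.end_bp) + "\n")
        hs.hotspot_frame(hotspot_list).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        hs.hotspot_frame(merged).to_csv(out / "hotspots_merged.tsv", sep="\t", index=False)
        if enrich:
            enrichment_frame(enrich).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if len(variant_summary):
            variant_summary.to_csv(out / "variant_candidates.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        result.out_dir = out
    return result


def interactions_frame(interactions: list) -> pd.DataFrame:
    """Peak table with the standard columns (method, gene, linkage group,
    flanking markers, LOD, PVE, additive and dominance effects)."""
    return pd.DataFrame(
        [
            {
                "method": i.method,
                "gene_id": i.gene_id,
                "linkage_group": i.linkage_group,
                "chrom": i.chrom,
                "left_bp": i.left_bp,
                "right_bp": i.right_bp,
                "lod": round(i.lod, 4),
                "pve_pct": round(i.pve, 4),
                "additive": round(i.additive, 6),
                "dominance": None if i.dominance is None else round(i.dominance, 6),
                "regulation": i.regulation,
            }
            for i in interactions
        ],
        columns=["method", "gene_id", "linkage_group", "chrom", "left_bp",
                 "right_bp", "lod", "pve_pct", "additive", "dominance",
                 "regulation"],
    )


def interactions_for_gene(consensus: list, gene_id: str) -> pd.DataFrame:
    """All consensus regions targeting one gene, one row per contributing
    method call (region, method, linkage group, markers, LOD, PVE, effects)."""
    rows = []
    for region in consensus:
        if region.gene_id != gene_id:
            continue
        for m in region.members:
            rows.append(
                {
                    "region": f"{region.chrom}:{region.start_bp:,}-{region.end_bp:,}",
                    "regulation": region.regulation,
                    "method": m.method,
                    "gene_id": gene_id,
                    "linkage_group": m.linkage_group,
                    "left_bp": m.left_bp,
                    "right_bp": m.right_bp,
                    "lod": m.lod,
                    "pve_pct": m.pve,
                    "additive": m.additive,
                    "dominance": m.dominance,
                }
            )
    if not rows:
        warnings.warn(f"no consensus interactions for gene {gene_id!r}", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=["region", "regulation", "method", "gene_id", "linkage_group",
                 "left_bp", "right_bp", "lod", "pve_pct", "additive", "dominance"],
    )
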