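"""Shared fixtures: small synthetic crosses built once per session."""

import numpy as np
import pandas as pd
import pytest

from eqtlcross import (
    GeneticMap,
    GenotypeMatrix,
    HotspotSpec,
    ScanGrid,
    SimulationConfig,
    build_map,
    simulate_expression,
    simulate_genotypes,
)
from eqtlcross.genmap import LinkageGroup


@pytest.fixture(scope="session")
def f2_cross():
    """Small F2 cross: 176 lines, 2 chromosomes x 20 markers, no planted
    effects (null expression)."""
    cfg = SimulationConfig(
        population_type="F2", n_lines=176, n_chromosomes=2,
        markers_per_chromosome=20, chromosome_length_bp=40_000_000,
        n_genes=120, cis_fraction=0.0, hotspot_specs=[], seed=101,
    )
    genotypes, markers = simulate_genotypes(cfg)
    counts, gene_ann, truth = simulate_expression(genotypes, markers, cfg)
    gmap = build_map(genotypes, markers)
    return dict(config=cfg, genotypes=genotypes, markers=markers,
                counts=counts, gene_ann=gene_ann, truth=truth, gmap=gmap)


@pytest.fixture(scope="session")
def ril_cross():
    """Small RIL cross with a planted hotspot and cis genes."""
    cfg = SimulationConfig(
        population_type="RIL", n_lines=162, n_chromosomes=2,
        markers_per_chromosome=25, chromosome_length_bp=50_000_000,
        n_genes=150, cis_fraction=0.05,
        hotspot_specs=[HotspotSpec(marker_index=12, n_targets=40, effect_sd=1.5)],
        seed=5,
    )
    genotypes, markers = simulate_genotypes(cfg)
    counts, gene_ann, truth = simulate_expression(genotypes, markers, cfg)
    gmap = build_map(genotypes, markers)
    return dict(config=cfg, genotypes=genotypes, markers=markers,
                counts=counts, gene_ann=gene_ann, truth=truth, gmap=gmap)


@pytest.fixture(scope="session")
def exact_map_f2():
    """F2 genotypes with a hand-built map whose marker cM positions are exact
    multiples of the scan step, so every marker sits on the scan grid."""
    cfg = SimulationConfig(
        population_type="F2", n_lines=150, n_chromosomes=1,
        markers_per_chromosome=10, chromosome_length_bp=20_000_000,
        n_genes=5, cis_fraction=0.0, hotspot_specs=[], seed=42,
    )
    genotypes, markers = simulate_genotypes(cfg)
    # true spacing: 2 Mb x 2.5 cM/Mb = 5 cM exactly
    table = pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "pos_bp": markers["pos_bp"],
            "pos_cM": 5.0 * np.arange(len(markers)),
        }
    )
    gmap = GeneticMap([LinkageGroup(name="GM01", chrom="GM01", table=table)])
    grid = ScanGrid(gmap, genotypes, step_cM=1.0)
    return dict(genotypes=genotypes, markers=markers, gmap=gmap, grid=grid)
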