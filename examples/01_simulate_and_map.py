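"""Simulate a biparental cross and build its linkage map.

Generates a small F2 population (176 lines, 2 chromosomes), estimates
adjacent-marker recombination fractions from the genotypes, and anchors the
Kosambi map to physical positions.  The printed lengths show the genetic
extent of each linkage group; with 20 markers spaced 2 Mb apart at
2.5 cM/Mb the truth is (20-1) x 5 = 95 cM, so the estimated lengths should
sit near that value.
"""

from eqtlcross import SimulationConfig, build_map, simulate_genotypes

config = SimulationConfig(
    population_type="F2", n_lines=176, n_chromosomes=2,
    markers_per_chromosome=20, chromosome_length_bp=40_000_000,
    n_genes=100, hotspot_specs=[], seed=1,
)
genotypes, markers = simulate_genotypes(config)
gmap = build_map(genotypes, markers, split_gap_cM=30.0)

print(f"{genotypes.n_lines} lines x {genotypes.n_markers} markers "
      f"({genotypes.population})")
for group in gmap:
    print(f"  linkage group {group.name}: {len(group)} markers, "
          f"{group.length_cm:.1f} cM")
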