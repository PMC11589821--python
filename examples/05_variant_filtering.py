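"""Candidate-SNP prioritization for candidate transcription factors.

Variants are simulated in two candidate TF genes, then pushed through the
filter cascade: keep MODERATE/HIGH consequences or 3'/5' UTR locations,
attach the SIFT verdict to missense variants (< 0.05 deleterious), and keep
only variants whose alternate allele is fixed in exactly one parental line.
The printed rows mimic a candidate-variant table: SNP position, reference /
parent-1 / parent-2 alleles ('*' marks a heterozygous parent), location, and
the missense verdict.  The planted deleterious missense always survives; the
planted LOW-consequence variant never does.
"""

from eqtlcross import (
    SimulationConfig, filter_candidates, merge_variant_tables,
    simulate_expression, simulate_genotypes, simulate_variants,
)

config = SimulationConfig(
    population_type="RIL", n_lines=162, n_chromosomes=2,
    markers_per_chromosome=10, n_genes=50, cis_fraction=0.0,
    hotspot_specs=[], seed=12,
)
genotypes, markers = simulate_genotypes(config)
_, gene_ann, _ = simulate_expression(genotypes, markers, config)

candidate_tfs = ["Gene00005", "Gene00017"]
tables = simulate_variants(config, candidate_tfs, gene_ann, n_per_gene=4)
merged = merge_variant_tables(tables.vcf, tables.annotation)
print(f"{len(merged)} simulated variants in {len(candidate_tfs)} candidate TFs")

kept = filter_candidates(merged, candidate_tfs)
print(f"{len(kept)} survive the cascade:")
for c in kept:
    p1 = "*" if c.parent1_het else c.parent1
    p2 = "*" if c.parent2_het else c.parent2
    verdict = f"Missense ({c.sift})" if c.sift != "N/A" else "N/A"
    print(f"  {c.gene_id}  {c.position}  {c.ref}>{c.alt}  "
          f"{c.ref}/{p1}/{p2}  {c.region:<6} {verdict}")
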