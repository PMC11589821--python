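"""End-to-end run: simulate -> map -> scan -> consensus -> hotspots.

A RIL cross is simulated with one trans regulator driving 60 target genes.
The pipeline scans every expressed gene with ICIM, IM and GCIM, keeps
signals found by at least two methods within 1 Mbp (the consensus merge),
counts trans interactions per regulating marker pair, and classifies the
pairs with the two-criterion percentile rule (count at the 95th/99th
percentile AND density at the 80th).  The printed hotspot should cover the
planted regulator's marker; because peaks scatter to the marker pairs on
either side of the regulator, its count is a large share of (not all of) the
60 planted targets.
"""

from eqtlcross import HotspotSpec, PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(
        population_type="RIL", n_lines=162, n_chromosomes=3,
        markers_per_chromosome=15, chromosome_length_bp=45_000_000,
        n_genes=160, cis_fraction=0.05,
        hotspot_specs=[HotspotSpec(marker_index=22, n_targets=60, effect_sd=1.5),
                       HotspotSpec(marker_index=5, n_targets=12, effect_sd=1.2)],
        seed=3,
    ),
    thresholds={"ICIM": 4.0, "IM": 4.0, "GCIM": 4.0},
    seed=3,
)
result = run_pipeline(config, out_dir="pipeline_run")

truth = result.truth.hotspot_markers[0]
print(f"planted regulator: {truth['chrom']}:{truth['pos_bp']:,}")
print("per-method interactions:", result.summary["interactions_per_method"])
print("consensus regions:", result.summary["consensus_regions_unique"])
for h in result.merged_hotspots:
    if h.hotspot_class != "none":
        print(f"  {h.name}  class={h.hotspot_class}  "
              f"n_trans={h.n_trans}  density={h.density:.2f}/kbp")
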