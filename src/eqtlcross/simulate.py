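"""Synthetic biparental-cross data with planted regulatory ground truth.

Generates the inputs the analysis pipeline consumes — genotypes, marker
positions, expression counts, gene annotation, and variants — with the
statistical structure the method assumes: F2 lines as two independent gametes
with crossovers placed by inter-marker recombination fractions, selfed RILs
through the standard 2r/(1+2r) expansion, negative-binomial counts with
per-line library sizes, planted cis effects at a gene's nearest marker, and
one or more trans-hotspot regulators each driving a block of target genes.

A :class:`GroundTruth` record of everything planted is returned alongside the
data so recovery tests can score the pipeline against what was simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GenotypeMatrix, inverse_kosambi

__all__ = [
    "SimulationConfig",
    "HotspotSpec",
    "GroundTruth",
    "ConfigurationError",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_variants",
    "VariantTables",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class HotspotSpec:
    """One planted trans regulator.

    marker_index indexes the genome-wide marker list (chromosome-major
    order); every target gene's expression responds to the genotype at that
    marker with the given additive effect in residual-SD units.
    """

    marker_index: int
    n_targets: int
    effect_sd: float


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cross.

    Defaults give a compact but structurally faithful cross; the
    ``f2_study``/``ril_study`` factories carry the full population scales
    (176 F2 / 162 RIL lines, ~1,600-2,700 markers, ~40k genes).
    """

    population_type: str = "F2"
    n_lines: int = 176
    n_chromosomes: int = 20
    markers_per_chromosome: int = 80
    chromosome_length_bp: int = 50_000_000
    n_genes: int = 2000
    cis_fraction: float = 0.05
    cis_effect_sd: float = 1.0
    dominance_sd: float = 0.0
    hotspot_specs: list[HotspotSpec] = field(
        default_factory=lambda: [HotspotSpec(marker_index=40, n_targets=100, effect_sd=1.5)]
    )
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (1_000_000.0, 3_000_000.0)
    recomb_rate_cm_per_mb: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.population_type not in ("F2", "RIL"):
            raise ConfigurationError(f"unknown population type {self.population_type!r}")
        for name in ("n_lines", "n_chromosomes", "markers_per_chromosome",
                     "chromosome_length_bp", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_lines < 2:
            raise ConfigurationError("n_lines must be >= 2")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ConfigurationError("cis_fraction must lie in [0, 1]")
        if not np.isfinite(self.cis_effect_sd) or not np.isfinite(self.dominance_sd):
            raise ConfigurationError("effect sizes must be finite")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must be a positive (lo, hi) pair")
        n_markers = self.n_chromosomes * self.markers_per_chromosome
        for h in self.hotspot_specs:
            if not (0 <= h.marker_index < n_markers):
                raise ConfigurationError(
                    f"hotspot marker index {h.marker_index} outside 0..{n_markers - 1}"
                )
            if not np.isfinite(h.effect_sd):
                raise ConfigurationError("hotspot effect sizes must be finite")
            if h.n_targets < 0:
                raise ConfigurationError("hotspot target counts must be >= 0")

    @classmethod
    def f2_study(cls, **overrides) -> "SimulationConfig":
        """Full F2 population scale: 176 lines, ~1,600 markers, ~39k genes."""
        base = dict(population_type="F2", n_lines=176, markers_per_chromosome=80,
                    n_genes=38_692)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def ril_study(cls, **overrides) -> "SimulationConfig":
        """Full RIL population scale: 162 lines, ~2,740 markers, ~40k genes."""
        base = dict(population_type="RIL", n_lines=162, markers_per_chromosome=137,
                    n_genes=40_218)
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Record of everything planted by the generator."""

    cis_gene_to_marker: dict[str, str]
    cis_effects: dict[str, float]
    hotspot_markers: list[dict]  # marker_id, chrom, pos_bp, effect_sd
    hotspot_targets: list[list[str]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _marker_layout(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers per chromosome with ids and physical positions."""
    rows = []
    m = config.markers_per_chromosome
    length = config.chromosome_length_bp
    for c in range(config.n_chromosomes):
        chrom = f"GM{c + 1:02d}"
        pos = np.round((np.arange(m) + 0.5) * length / m).astype(np.int64)
        for j in range(m):
            rows.append((f"{chrom}_M{j + 1:03d}", chrom, int(pos[j])))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"])


def _adjacent_r(positions_bp: np.ndarray, rate_cm_per_mb: float) -> np.ndarray:
    """Meiotic recombination fraction between adjacent markers from physical
    spacing via a uniform cM/Mb rate and the inverse Kosambi function."""
    d_cm = np.diff(positions_bp) / 1e6 * rate_cm_per_mb
    return np.asarray(inverse_kosambi(d_cm), dtype=float)


def _gamete_alleles(rng: np.random.Generator, n_lines: int, r: np.ndarray) -> np.ndarray:
    """One gamete per line along a chromosome: alleles in {0,1}, crossovers as
    independent inter-marker recombination events (no interference)."""
    n_markers = len(r) + 1
    start = rng.integers(0, 2, size=(n_lines, 1))
    rec = (rng.random(size=(n_lines, len(r))) < r[None, :]).astype(np.int8)
    flips = np.concatenate([start, rec], axis=1)
    return np.cumsum(flips, axis=1) % 2


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the genotype matrix and marker positions for one cross.

    F2 lines are two independent gametes (expected 1:2:1 per marker); RILs
    are a single near-homozygous chain whose adjacent-marker recombination is
    the selfed-RIL expansion r* = 2r/(1+2r) of the meiotic fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = _marker_layout(config)
    line_ids = [f"L{i + 1:04d}" for i in range(config.n_lines)]

    blocks = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        r = _adjacent_r(sub["pos_bp"].to_numpy(), config.recomb_rate_cm_per_mb)
        if config.population_type == "F2":
            g1 = _gamete_alleles(rng, config.n_lines, r)
            g2 = _gamete_alleles(rng, config.n_lines, r)
            codes = (g1 + g2).astype(np.int8)  # 0=A, 1=H, 2=B
        else:
            r_star = 2.0 * r / (1.0 + 2.0 * r)
            alleles = _gamete_alleles(rng, config.n_lines, r_star)
            codes = (2 * alleles).astype(np.int8)  # 0=A, 2=B
        blocks.append(codes)

    genotypes = GenotypeMatrix(
        line_ids=line_ids,
        marker_ids=markers["marker_id"].tolist(),
        codes=np.concatenate(blocks, axis=1),
        population=config.population_type,
    )
    return genotypes, markers


def _gene_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = [f"GM{c + 1:02d}" for c in range(config.n_chromosomes)]
    gene_ids = [f"Gene{i + 1:05d}" for i in range(config.n_genes)]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": rng.choice(chroms, size=config.n_genes),
            "tss_bp": rng.integers(1, config.chromosome_length_bp, size=config.n_genes),
            "strand": rng.choice(["+", "-"], size=config.n_genes),
        }
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    marker_positions: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a genes x lines count matrix with planted genotype effects.

    Gene baselines are shared log-normal (heavy-tailed, as median-of-ratios
    normalization expects); each gene's log-mean shifts by its planted
    additive effect times the line's genotype at the causal marker, effects
    being expressed in units of the gene's residual SD on the log scale;
    counts are negative binomial with the configured dispersion and per-line
    library-size targets drawn uniformly from ``library_size_range``.

    Returns (counts, gene_annotation, ground_truth).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    genes = _gene_layout(config, rng)
    n_genes, n_lines = config.n_genes, genotypes.n_lines

    total_targets = sum(h.n_targets for h in config.hotspot_specs)
    n_cis = int(round(config.cis_fraction * n_genes))
    if n_cis + total_targets > n_genes:
        raise ConfigurationError(
            f"{total_targets} hotspot targets + {n_cis} cis genes exceed n_genes={n_genes}"
        )

    order = rng.permutation(n_genes)
    cis_idx = order[:n_cis]
    cursor = n_cis
    hotspot_target_idx: list[np.ndarray] = []
    for h in config.hotspot_specs:
        hotspot_target_idx.append(order[cursor : cursor + h.n_targets])
        cursor += h.n_targets

    # baseline abundances: shared log-normal across genes
    base = rng.lognormal(mean=np.log(50.0), sigma=1.5, size=n_genes)
    rel = base / base.sum()
    lib = rng.uniform(*config.library_size_range, size=n_lines)
    mu0 = np.outer(rel, lib)  # genes x lines, null means

    # additive genotype covariate per line for any causal marker: A=-1, H=0, B=+1
    def marker_x(marker_index: int) -> np.ndarray:
        return (genotypes.codes[:, marker_index].astype(float) - 1.0)

    mean_counts = mu0.mean(axis=1)
    sigma_log = np.sqrt(config.dispersion + 1.0 / np.maximum(mean_counts, 1e-9))

    log_shift = np.zeros((n_genes, n_lines))
    cis_map: dict[str, str] = {}
    cis_eff: dict[str, float] = {}
    marker_chrom = marker_positions.set_index("marker_id")

    # each planted effect's direction is random: regulators both activate and
    # repress targets, which also keeps the count composition balanced
    for gi in cis_idx:
        chrom = genes["chrom"].iloc[gi]
        sub = marker_positions[marker_positions["chrom"] == chrom]
        nearest = (sub["pos_bp"] - genes["tss_bp"].iloc[gi]).abs().idxmin()
        mid = marker_positions.loc[nearest, "marker_id"]
        a = float(rng.choice([-1.0, 1.0])) * config.cis_effect_sd * sigma_log[gi]
        x = marker_x(genotypes.marker_index(mid))
        log_shift[gi] += a * x
        if config.dominance_sd and config.population_type == "F2":
            log_shift[gi] += config.dominance_sd * sigma_log[gi] * (x == 0)
        cis_map[genes["gene_id"].iloc[gi]] = mid
        cis_eff[genes["gene_id"].iloc[gi]] = float(a)

    hotspot_records = []
    hotspot_targets: list[list[str]] = []
    for h, t_idx in zip(config.hotspot_specs, hotspot_target_idx):
        mid = genotypes.marker_ids[h.marker_index]
        x = marker_x(h.marker_index)
        for gi in t_idx:
            sign = float(rng.choice([-1.0, 1.0]))
            log_shift[gi] += sign * h.effect_sd * sigma_log[gi] * x
        hotspot_records.append(
            {
                "marker_id": mid,
                "chrom": str(marker_chrom.loc[mid, "chrom"]),
                "pos_bp": int(marker_chrom.loc[mid, "pos_bp"]),
                "effect_sd": float(h.effect_sd),
            }
        )
        hotspot_targets.append([genes["gene_id"].iloc[gi] for gi in t_idx])

    mu = mu0 * np.exp(log_shift)
    alpha = config.dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / alpha
        counts = rng.negative_binomial(shape, shape / (shape + mu))

    counts_df = pd.DataFrame(counts, index=genes["gene_id"], columns=genotypes.line_ids)
    counts_df.index.name = "gene_id"
    truth = GroundTruth(
        cis_gene_to_marker=cis_map,
        cis_effects=cis_eff,
        hotspot_markers=hotspot_records,
        hotspot_targets=hotspot_targets,
    )
    return counts_df, genes, truth


CONSEQUENCE_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_REGIONS = ("CDS", "3'UTR", "5'UTR", "other")
_BASES = ("A", "C", "G", "T")


@dataclass
class VariantTables:
    """A VCF-shaped variant table plus its companion annotation table."""

    vcf: pd.DataFrame  # chrom, pos, id, ref, alt
    annotation: pd.DataFrame  # variant_id, gene_id, consequence, region, sift_score, parent1, parent2

    def write(self, vcf_path, annotation_path) -> None:
        from .variants import write_vcf

        write_vcf(self.vcf, vcf_path)
        self.annotation.to_csv(annotation_path, sep="\t", index=False)


def simulate_variants(
    config: SimulationConfig,
    candidate_genes: list[str],
    gene_annotation: pd.DataFrame,
    n_per_gene: int = 3,
    plant_exemplars: bool = True,
) -> VariantTables:
    """Simulate variants in candidate genes with VEP/SIFT-style annotations.

    Consequence classes are drawn from {HIGH, MODERATE, LOW, MODIFIER}, UTR
    locations and SIFT scores are attached, and per-parent alleles are drawn
    so both parental patterns (single-parent and shared alternate) occur.
    When ``plant_exemplars`` is set, the first candidate gene receives one
    deleterious missense variant carried by a single parent (which must
    survive the downstream filter cascade) and one LOW-consequence variant
    (which must be removed by it).
    """
    if not candidate_genes:
        raise ConfigurationError("candidate gene list must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    ann = gene_annotation.set_index("gene_id")

    rows_vcf, rows_ann = [], []
    counter = 0

    def add(gene, consequence, region, sift, parent1, parent2, ref=None, alt=None):
        nonlocal counter
        counter += 1
        chrom = str(ann.loc[gene, "chrom"])
        pos = int(ann.loc[gene, "tss_bp"]) + int(rng.integers(0, 5000))
        if ref is None:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
        vid = f"var{counter:04d}"
        rows_vcf.append((chrom, pos, vid, ref, alt))
        rows_ann.append((vid, gene, consequence, region, sift,
                         parent1.format(ref=ref, alt=alt),
                         parent2.format(ref=ref, alt=alt)))

    if plant_exemplars:
        g0 = candidate_genes[0]
        add(g0, "MODERATE", "CDS", 0.01, "{alt}", "{ref}")  # deleterious missense, single parent
        add(g0, "LOW", "CDS", None, "{alt}", "{ref}")       # synonymous-style, filtered out

    for gene in candidate_genes:
        for _ in range(n_per_gene):
            consequence = rng.choice(CONSEQUENCE_CLASSES)
            region = rng.choice(_REGIONS)
            sift = float(np.round(rng.random(), 3)) if consequence == "MODERATE" else None
            pattern = rng.choice(["single", "shared", "het"])
            if pattern == "single":
                p1, p2 = "{alt}", "{ref}"
            elif pattern == "shared":
                p1, p2 = "{alt}", "{alt}"
            else:
                p1, p2 = "{ref}/{alt}", "{ref}"
            add(gene, consequence, region, sift, p1, p2)

    vcf = pd.DataFrame(rows_vcf, columns=["chrom", "pos", "id", "ref", "alt"])
    vcf = vcf.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    annotation = pd.DataFrame(
        rows_ann,
        columns=["variant_id", "gene_id", "consequence", "region",
                 "sift_score", "parent1", "parent2"],
    )
    return VariantTables(vcf=vcf, annotation=annotation)
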