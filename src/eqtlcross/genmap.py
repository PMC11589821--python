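"""Linkage-map construction for biparental crosses.

Markers are anchored to their physical positions; genetic distances between
adjacent markers come from estimated recombination fractions passed through
the Kosambi mapping function, and a chromosome is split into separate linkage
groups wherever an adjacent gap exceeds a configurable threshold (30 cM by
default, matching common practice for sparse genotyping-by-sequencing maps).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneticMap",
    "LinkageGroup",
    "kosambi_cm",
    "inverse_kosambi",
    "estimate_adjacent_r",
    "build_map",
]

# integer codes used throughout: A=0, H=1, B=2, missing=-1
CODE = {"A": 0, "H": 1, "B": 2}
DECODE = {0: "A", 1: "H", 2: "B", -1: "-"}
MISSING = -1


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Map distance in centiMorgans for recombination fraction ``r``.

    d = 25 * ln((1 + 2r) / (1 - 2r)).  Valid for 0 <= r < 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def inverse_kosambi(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a Kosambi map distance in cM.

    Inverse of :func:`kosambi_cm`: r = tanh(d / 50) / 2.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GenotypeMatrix:
    """Coded genotype calls for a mapping population.

    ``codes`` is lines x markers, int8, with A=0, H=1, B=2 and -1 for
    missing.  RIL matrices must not contain H after filtering.
    """

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    population: str  # "F2" or "RIL"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("codes shape inconsistent with line/marker ids")
        if self.population not in ("F2", "RIL"):
            raise ValueError(f"unknown population type {self.population!r}")
        if self.population == "RIL" and np.any(self.codes == 1):
            raise ValueError("RIL genotypes may not contain heterozygote calls")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def to_frame(self) -> pd.DataFrame:
        """Lines x markers DataFrame of letter calls (A/H/B, '-' missing)."""
        letters = np.vectorize(DECODE.get)(self.codes)
        return pd.DataFrame(letters, index=self.line_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, population: str) -> "GenotypeMatrix":
        codes = frame.apply(lambda col: col.map(lambda v: CODE.get(v, MISSING)))
        return cls(
            line_ids=[str(i) for i in frame.index],
            marker_ids=[str(c) for c in frame.columns],
            codes=codes.to_numpy(dtype=np.int8),
            population=population,
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="line")

    @classmethod
    def read_tsv(cls, path, population: str) -> "GenotypeMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="line", dtype=str)
        return cls.from_frame(frame, population)


def estimate_adjacent_r(
    genotypes: GenotypeMatrix,
    marker_a: str | int,
    marker_b: str | int,
    population: str | None = None,
    min_lines: int = 10,
    max_em_iter: int = 200,
    tol: float = 1e-9,
) -> float:
    """Estimate the recombination fraction between two markers.

    RIL: the observed recombinant fraction r_obs between near-homozygous
    inbred lines is inflated by repeated selfing; the meiotic fraction is
    recovered through the standard expansion r_obs = 2r/(1+2r), i.e.
    r = r_obs / (2 - 2 r_obs).

    F2: maximum likelihood over the 9 two-marker genotype classes by EM,
    treating each line as two independent gametes; the double heterozygote
    class is the only one with latent phase.

    Result is clamped to [0, 0.4999] so it stays inside the Kosambi domain.
    """
    population = population or genotypes.population
    ia = marker_a if isinstance(marker_a, int) else genotypes.marker_index(marker_a)
    ib = marker_b if isinstance(marker_b, int) else genotypes.marker_index(marker_b)
    ga = genotypes.codes[:, ia]
    gb = genotypes.codes[:, ib]
    keep = (ga != MISSING) & (gb != MISSING)
    n = int(keep.sum())
    if n < min_lines:
        raise ValueError(
            f"only {n} lines share non-missing calls at the two markers "
            f"(need >= {min_lines})"
        )
    ga, gb = ga[keep], gb[keep]

    if population == "RIL":
        r_obs = float(np.mean(ga != gb))
        r_obs = min(r_obs, 0.999)  # guard the algebra below
        r = r_obs / (2.0 - 2.0 * r_obs)
        return float(np.clip(r, 0.0, 0.4999))

    # F2 EM: expected count of recombinant gametes per genotype-pair class.
    # Classes other than the double heterozygote have a fixed recombinant
    # gamete count; (H,H) is a mixture of 0 (coupling) and 2 (repulsion).
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (ga, gb), 1.0)
    fixed_rec = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    n_hh = counts[1, 1]
    r = 0.25
    for _ in range(max_em_iter):
        # E-step: expected recombinant gametes in the (H,H) class
        denom = r * r + (1 - r) * (1 - r)
        e_hh = 0.0 if denom == 0 else 2.0 * r * r / denom
        total_rec = float(np.sum(counts * fixed_rec)) - 0.0 + n_hh * e_hh
        # M-step
        r_new = total_rec / (2.0 * n)
        r_new = float(np.clip(r_new, 0.0, 0.4999))
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(np.clip(r, 0.0, 0.4999))


@dataclass
class LinkageGroup:
    """Ordered markers of one linkage group with physical and genetic positions."""

    name: str
    chrom: str
    table: pd.DataFrame = field(repr=False)  # marker_id, pos_bp, pos_cM

    def __len__(self) -> int:
        return len(self.table)

    @property
    def length_cm(self) -> float:
        return float(self.table["pos_cM"].iloc[-1]) if len(self.table) else 0.0


@dataclass
class GeneticMap:
    """A linkage map: ordered linkage groups anchored to physical positions."""

    groups: list[LinkageGroup]

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def n_markers(self) -> int:
        return sum(len(g) for g in self.groups)

    def group(self, name: str) -> LinkageGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            t = g.table.copy()
            t.insert(0, "linkage_group", g.name)
            t.insert(1, "chrom", g.chrom)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        frame = pd.read_csv(path, sep="\t")
        groups = []
        for name, sub in frame.groupby("linkage_group", sort=False):
            chrom = str(sub["chrom"].iloc[0])
            groups.append(
                LinkageGroup(
                    name=str(name),
                    chrom=chrom,
                    table=sub[["marker_id", "pos_bp", "pos_cM"]].reset_index(drop=True),
                )
            )
        return cls(groups)


def _group_names(chrom: str, n_groups: int) -> list[str]:
    if n_groups == 1:
        return [chrom]
    return [f"{chrom}{string.ascii_lowercase[i]}" for i in range(n_groups)]


def build_map(
    genotypes: GenotypeMatrix,
    marker_positions: pd.DataFrame,
    split_gap_cM: float = 30.0,
) -> GeneticMap:
    """Build a physically anchored linkage map.

    ``marker_positions`` needs columns marker_id, chrom, pos_bp.  Markers are
    ordered by (chrom, pos_bp); adjacent recombination fractions are estimated
    from the genotypes and converted to Kosambi cM; cumulative positions start
    at 0 per group, and a new group begins wherever an adjacent gap strictly
    exceeds ``split_gap_cM`` (a gap of exactly the threshold stays joined).
    Split groups get a letter suffix ("13a", "13b" style).
    """
    pos = marker_positions.copy()
    required = {"marker_id", "chrom", "pos_bp"}
    if not required.issubset(pos.columns):
        raise ValueError(f"marker_positions must have columns {sorted(required)}")
    missing = set(genotypes.marker_ids) - set(pos["marker_id"].astype(str))
    if missing:
        raise ValueError(f"markers without physical position: {sorted(missing)[:5]}")

    pos = pos[pos["marker_id"].astype(str).isin(genotypes.marker_ids)]
    dup = pos.duplicated(subset=["chrom", "pos_bp"], keep=False)
    if dup.any():
        warnings.warn(
            "duplicate physical positions on a chromosome; ties broken by marker id",
            stacklevel=2,
        )
    pos = pos.sort_values(["chrom", "pos_bp", "marker_id"], kind="mergesort")

    groups: list[LinkageGroup] = []
    for chrom, sub in pos.groupby("chrom", sort=True):
        marker_ids = sub["marker_id"].astype(str).tolist()
        bp = sub["pos_bp"].to_numpy()
        # adjacent distances
        dists = np.zeros(len(marker_ids))
        for i in range(1, len(marker_ids)):
            r = estimate_adjacent_r(genotypes, marker_ids[i - 1], marker_ids[i])
            dists[i] = kosambi_cm(r)
        # split wherever gap strictly exceeds the threshold
        break_after = np.flatnonzero(dists > split_gap_cM)  # index i: gap before marker i
        bounds = [0, *break_after.tolist(), len(marker_ids)]
        chrom_groups = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            cm = np.concatenate([[0.0], np.cumsum(dists[a + 1 : b])])
            chrom_groups.append(
                pd.DataFrame(
                    {
                        "marker_id": marker_ids[a:b],
                        "pos_bp": bp[a:b],
                        "pos_cM": cm,
                    }
                )
            )
        names = _group_names(str(chrom), len(chrom_groups))
        for name, table in zip(names, chrom_groups):
            groups.append(LinkageGroup(name=name, chrom=str(chrom), table=table))
    return GeneticMap(groups)
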