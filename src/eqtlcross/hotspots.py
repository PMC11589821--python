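"""Trans-regulatory hotspot detection by a two-criterion percentile rule.

Each distinct regulating marker-pair region accumulates the trans
interactions it drives.  A region is a major hotspot when its interaction
count reaches the 99th percentile of all regions' counts in that population
AND its interaction density (interactions per kbp of the marker-pair span)
reaches the 80th percentile of all densities; it is a minor hotspot when its
count sits between the 95th and 99th percentiles with the same density
requirement.  Both criteria are mandatory — a region above the count cut but
below the density cut is not a hotspot.  Neighboring hotspots sharing a
boundary marker are merged, and regions are named
``<TAG>_<CHROM>:<start>-<end>`` with thousands-separated coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusRegion

__all__ = [
    "Hotspot",
    "count_by_marker_pair",
    "interaction_density",
    "classify_hotspots",
    "merge_adjacent",
    "region_name",
    "parse_region_name",
]

_CLASS_RANK = {"none": 0, "minor": 1, "major": 2}


def region_name(population_tag: str, chrom: str, start_bp: int, end_bp: int) -> str:
    """Canonical region name, e.g. ``F2_GM18:1,434,182-1,935,386``."""
    return f"{population_tag}_{chrom}:{start_bp:,}-{end_bp:,}"


_NAME_RE = re.compile(r"^(?P<tag>[^_]+)_(?P<chrom>[^:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def parse_region_name(name: str) -> tuple[str, str, int, int]:
    """Inverse of :func:`region_name`."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"bad region name: {name!r}")
    return (
        m["tag"],
        m["chrom"],
        int(m["start"].replace(",", "")),
        int(m["end"].replace(",", "")),
    )


@dataclass
class Hotspot:
    """A marker-pair region with its trans-interaction load and class."""

    population: str  # "F2" or "RIL"
    chrom: str
    left_bp: int
    right_bp: int
    n_trans: int
    hotspot_class: str = "none"  # major | minor | none

    @property
    def size_bp(self) -> int:
        return self.right_bp - self.left_bp

    @property
    def density(self) -> float:
        """Interactions per kbp; undefined (nan) for zero-width regions."""
        if self.size_bp <= 0:
            return float("nan")
        return self.n_trans / (self.size_bp / 1000.0)

    @property
    def name(self) -> str:
        return region_name(self.population, self.chrom, self.left_bp, self.right_bp)


def count_by_marker_pair(consensus_trans: list[ConsensusRegion]) -> pd.DataFrame:
    """Number of trans interactions per distinct regulating region.

    Returns a frame with columns chrom, left_bp, right_bp, n_trans — one row
    per distinct (chromosome, left, right) region, counting the trans
    interactions (target genes) it regulates.
    """
    if not consensus_trans:
        return pd.DataFrame(columns=["chrom", "left_bp", "right_bp", "n_trans"])
    rows = pd.DataFrame(
        {
            "chrom": [r.chrom for r in consensus_trans],
            "left_bp": [r.start_bp for r in consensus_trans],
            "right_bp": [r.end_bp for r in consensus_trans],
        }
    )
    out = (
        rows.groupby(["chrom", "left_bp", "right_bp"], sort=True)
        .size()
        .rename("n_trans")
        .reset_index()
    )
    return out


def interaction_density(count: int, left_bp: int, right_bp: int) -> float:
    """Average number of trans interactions per kbp of the marker-pair span."""
    if right_bp <= left_bp:
        raise ValueError("density undefined for zero- or negative-width regions")
    return count / ((right_bp - left_bp) / 1000.0)


def classify_hotspots(
    regions_with_counts: pd.DataFrame,
    population_tag: str,
    count_pct_minor: float = 95.0,
    count_pct_major: float = 99.0,
    density_pct: float = 80.0,
) -> list[Hotspot]:
    """Classify every region as major / minor / none.

    Count thresholds are the stated percentiles of per-region counts across
    all regions of the population; the density threshold is the stated
    percentile of all defined densities.  Percentiles use linear
    interpolation; "above the Nth percentile" is implemented inclusively
    (>= threshold).  Zero-width regions stay in the count pool but have
    undefined density and therefore can never satisfy the density criterion.
    """
    df = regions_with_counts
    if len(df) < 2:
        raise ValueError("percentile classification needs >= 2 regions")
    counts = df["n_trans"].to_numpy(dtype=float)
    widths = (df["right_bp"] - df["left_bp"]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        densities = np.where(widths > 0, counts / (widths / 1000.0), np.nan)
    if np.isnan(densities).any():
        warnings.warn(
            "zero-width regions excluded from the density percentile pool",
            stacklevel=2,
        )
    count_minor = float(np.percentile(counts, count_pct_minor))
    count_major = float(np.percentile(counts, count_pct_major))
    pool = densities[~np.isnan(densities)]
    density_cut = float(np.percentile(pool, density_pct)) if pool.size else np.inf

    hotspots = []
    for row, count, dens in zip(df.itertuples(index=False), counts, densities):
        dense_enough = not np.isnan(dens) and dens >= density_cut
        if count >= count_major and dense_enough:
            cls = "major"
        elif count_minor <= count < count_major and dense_enough:
            cls = "minor"
        else:
            cls = "none"
        hotspots.append(
            Hotspot(
                population=population_tag,
                chrom=str(row.chrom),
                left_bp=int(row.left_bp),
                right_bp=int(row.right_bp),
                n_trans=int(count),
                hotspot_class=cls,
            )
        )
    return hotspots


def merge_adjacent(hotspots: list[Hotspot]) -> list[Hotspot]:
    """Merge hotspots on the same chromosome that share a boundary marker.

    Counts are summed, density recomputed from the merged span, and the
    merged class is the stronger of the two.  Regions classified ``none``
    pass through untouched.
    """
    real = sorted(
        (h for h in hotspots if h.hotspot_class != "none"),
        key=lambda h: (h.population, h.chrom, h.left_bp, h.right_bp),
    )
    passthrough = [h for h in hotspots if h.hotspot_class == "none"]
    merged: list[Hotspot] = []
    for h in real:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.population == h.population
            and last.chrom == h.chrom
            and last.right_bp == h.left_bp
        ):
            merged[-1] = Hotspot(
                population=last.population,
                chrom=last.chrom,
                left_bp=last.left_bp,
                right_bp=h.right_bp,
                n_trans=last.n_trans + h.n_trans,
                hotspot_class=max(
                    (last.hotspot_class, h.hotspot_class), key=_CLASS_RANK.get
                ),
            )
        else:
            merged.append(h)
    return merged + passthrough


def hotspot_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Tabular hotspot view: name, span, size, count, density, class."""
    return pd.DataFrame(
        {
            "name": [h.name for h in hotspots],
            "population": [h.population for h in hotspots],
            "chrom": [h.chrom for h in hotspots],
            "left_bp": [h.left_bp for h in hotspots],
            "right_bp": [h.right_bp for h in hotspots],
            "size_bp": [h.size_bp for h in hotspots],
            "n_trans": [h.n_trans for h in hotspots],
            "density_per_kbp": [round(h.density, 2) if h.size_bp > 0 else np.nan
                                for h in hotspots],
            "class": [h.hotspot_class for h in hotspots],
        }
    )
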