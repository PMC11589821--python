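"""eQTL scan engines and permutation thresholds.

Three scan strategies over a genes x lines expression matrix on a linkage
map:

* ``im_scan`` — interval mapping by Haley-Knott regression: at each grid
  position the putative QTL genotype expectation is computed from the
  flanking markers and recombination fractions, the phenotype is regressed
  on additive (and, for F2, dominance) scores, and LOD =
  (n/2) * log10(RSS0/RSS1).
* ``icim_scan`` — inclusive composite interval mapping: stepwise
  forward-backward marker (cofactor) selection, phenotype adjustment by the
  fitted cofactor contributions excluding the flanking markers of the
  interval being scanned, then interval mapping on the adjusted phenotype.
* ``gcim_scan`` — a simplified genome-wide composite interval mapping
  stand-in: a genome-wide scan with polygenic control (top-k cofactors, or a
  REML variance-component polygenic term with a marker-derived kinship),
  followed by a penalized joint refit of candidate loci.

``permutation_threshold`` draws the genome-wide null by permuting a random
sample of transcripts and pooling the per-permutation maximum LODs; the
global threshold is the (1 - alpha) empirical percentile of the pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import Lasso

from .genmap import GeneticMap, GenotypeMatrix, inverse_kosambi

__all__ = [
    "EqtlInteraction",
    "ScanProfile",
    "ScanGrid",
    "im_scan",
    "icim_scan",
    "gcim_scan",
    "scan_genes_im",
    "permutation_threshold",
    "PermutationResult",
]

_MISS = 3  # table index for a missing flank


@dataclass
class EqtlInteraction:
    """One gene x genomic-region association call."""

    gene_id: str
    method: str  # ICIM | IM | GCIM
    linkage_group: str
    chrom: str
    left_bp: int
    right_bp: int
    lod: float
    pve: float  # percent variance explained
    additive: float
    dominance: float | None  # None for RIL
    peak_cM: float = 0.0
    regulation: str | None = None  # "cis"/"trans", set by the consensus stage

    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.left_bp, self.right_bp)


@dataclass
class ScanProfile:
    """LOD (and fitted effect) along the scan grid for one gene."""

    gene_id: str
    method: str
    table: pd.DataFrame  # linkage_group, pos_cM, left_marker, right_marker, lod


def _f2_tables(r1: float, r2: float, r12: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional QTL genotype scores for every observed flanking-genotype
    pair in an F2, by enumeration of ordered gamete pairs.

    Returns (x, z, valid) each indexed [left_code, right_code] with codes
    0=A, 1=H, 2=B, 3=missing.  x = P(BB) - P(AA), z = P(H).  A line is
    ``valid`` unless both flanks are uninformative.
    """
    t1 = np.array([[1 - r1, r1], [r1, 1 - r1]])
    t2 = np.array([[1 - r2, r2], [r2, 1 - r2]])
    t12 = np.array([[1 - r12, r12], [r12, 1 - r12]])
    x = np.zeros((4, 4))
    z = np.zeros((4, 4))
    valid = np.zeros((4, 4), dtype=bool)
    for gl in range(4):
        for gr in range(4):
            pq = np.zeros(3)
            tot = 0.0
            for l1 in (0, 1):
                for rr1 in (0, 1):
                    for l2 in (0, 1):
                        for rr2 in (0, 1):
                            if gl < 3 and l1 + l2 != gl:
                                continue
                            if gr < 3 and rr1 + rr2 != gr:
                                continue
                            w = 0.25 * t12[l1, rr1] * t12[l2, rr2]
                            if w <= 0.0:
                                continue
                            q1 = np.array([t1[l1, 0] * t2[0, rr1], t1[l1, 1] * t2[1, rr1]])
                            q2 = np.array([t1[l2, 0] * t2[0, rr2], t1[l2, 1] * t2[1, rr2]])
                            if q1.sum() <= 0 or q2.sum() <= 0:
                                continue
                            q1 /= q1.sum()
                            q2 /= q2.sum()
                            joint = np.outer(q1, q2)
                            pq[0] += w * joint[0, 0]
                            pq[1] += w * (joint[0, 1] + joint[1, 0])
                            pq[2] += w * joint[1, 1]
                            tot += w
            if tot > 0:
                pq /= tot
                x[gl, gr] = pq[2] - pq[0]
                z[gl, gr] = pq[1]
            valid[gl, gr] = not (gl == 3 and gr == 3) and tot > 0
    return x, z, valid


def _ril_tables(r1_star: float, r2_star: float) -> tuple[np.ndarray, np.ndarray]:
    """Conditional additive score for a two-state RIL chain.

    Indexed [left_code, right_code] with codes 0=A, 2=B, 3=missing (code 1
    treated as missing).  x = P(B) - P(A).
    """
    t1 = np.array([[1 - r1_star, r1_star], [r1_star, 1 - r1_star]])
    t2 = np.array([[1 - r2_star, r2_star], [r2_star, 1 - r2_star]])
    x = np.zeros((4, 4))
    valid = np.zeros((4, 4), dtype=bool)
    allele = {0: 0, 2: 1}
    for gl in (0, 2, 3):
        for gr in (0, 2, 3):
            w = np.zeros(2)
            for q in (0, 1):
                pl = 0.5 if gl == 3 else t1[allele[gl], q]
                pr = 1.0 if gr == 3 else t2[q, allele[gr]]
                w[q] = pl * pr
            s = w.sum()
            if s > 0:
                w /= s
                x[gl, gr] = w[1] - w[0]
            valid[gl, gr] = not (gl == 3 and gr == 3) and s > 0
    return x, valid


@dataclass
class _GridPosition:
    linkage_group: str
    chrom: str
    pos_cM: float
    left_marker: str
    right_marker: str
    left_bp: int
    right_bp: int
    x: np.ndarray
    z: np.ndarray | None
    valid: np.ndarray
    basis: np.ndarray = field(default=None, repr=False)  # orthonormal, full-data path


class ScanGrid:
    """Precomputed scan positions and Haley-Knott designs for one map.

    Built once per (map, genotypes, step); reused across genes and
    permutations so the expensive flanking-probability tables are computed a
    single time.
    """

    def __init__(self, gmap: GeneticMap, genotypes: GenotypeMatrix, step_cM: float = 1.0):
        if step_cM <= 0:
            raise ValueError("step_cM must be positive")
        self.gmap = gmap
        self.genotypes = genotypes
        self.step_cM = float(step_cM)
        self.positions: list[_GridPosition] = []
        self.n_lines = genotypes.n_lines
        self._build()

    def _codes_for(self, marker_id: str) -> np.ndarray:
        codes = self.genotypes.codes[:, self.genotypes.marker_index(marker_id)].astype(int)
        codes = np.where(codes < 0, _MISS, codes)
        if self.genotypes.population == "RIL":
            codes = np.where(codes == 1, _MISS, codes)
        return codes

    def _build(self) -> None:
        is_f2 = self.genotypes.population == "F2"
        for lg in self.gmap:
            cm = lg.table["pos_cM"].to_numpy(dtype=float)
            bp = lg.table["pos_bp"].to_numpy()
            markers = lg.table["marker_id"].tolist()
            codes = {m: self._codes_for(m) for m in markers}
            if len(markers) == 1:
                grid = np.array([0.0])
            else:
                grid = np.arange(0.0, cm[-1] + 1e-9, self.step_cM)
                if grid[-1] < cm[-1] - 1e-9:
                    grid = np.append(grid, cm[-1])
            for pos in grid:
                if len(markers) == 1:
                    i = j = 0
                    d1 = d2 = 0.0
                else:
                    i = int(np.clip(np.searchsorted(cm, pos, side="right") - 1, 0, len(cm) - 2))
                    j = i + 1
                    d1 = max(pos - cm[i], 0.0)
                    d2 = max(cm[j] - pos, 0.0)
                r1 = float(inverse_kosambi(d1))
                r2 = float(inverse_kosambi(d2))
                gl = codes[markers[i]]
                gr = codes[markers[j]] if j != i else np.full(self.n_lines, _MISS)
                if is_f2:
                    r12 = float(inverse_kosambi(d1 + d2))
                    xt, zt, vt = _f2_tables(r1, r2, r12)
                    x = xt[gl, gr]
                    z = zt[gl, gr]
                else:
                    r1s = 2 * r1 / (1 + 2 * r1)
                    r2s = 2 * r2 / (1 + 2 * r2)
                    xt, vt = _ril_tables(r1s, r2s)
                    x = xt[gl, gr]
                    z = None
                valid = vt[gl, gr]
                gp = _GridPosition(
                    linkage_group=lg.name,
                    chrom=lg.chrom,
                    pos_cM=float(pos),
                    left_marker=markers[i],
                    right_marker=markers[j],
                    left_bp=int(bp[i]),
                    right_bp=int(bp[j]),
                    x=np.asarray(x, dtype=float),
                    z=None if z is None else np.asarray(z, dtype=float),
                    valid=np.asarray(valid, dtype=bool),
                )
                gp.basis = self._orthobasis(gp)
                self.positions.append(gp)

    @staticmethod
    def _design_columns(gp: _GridPosition) -> np.ndarray:
        cols = [gp.x] if gp.z is None else [gp.x, gp.z]
        return np.column_stack(cols)

    def _orthobasis(self, gp: _GridPosition) -> np.ndarray:
        """Orthonormal basis of the centered design at a position, computed
        on all lines (fast path when no line must be dropped)."""
        d = self._design_columns(gp)
        dc = d - d.mean(axis=0)
        q, r = np.linalg.qr(dc)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        return q[:, keep]

    # ------------------------------------------------------------------
    def lod_matrix(self, y: np.ndarray) -> np.ndarray:
        """LOD at every grid position for one or many phenotypes.

        ``y`` is (n_lines,) or (n_lines, n_phenotypes); returns
        (n_positions, n_phenotypes).
        """
        y = np.asarray(y, dtype=float)
        squeeze = y.ndim == 1
        Y = y[:, None] if squeeze else y
        n = self.n_lines
        Yc = Y - Y.mean(axis=0)
        rss0 = np.einsum("ij,ij->j", Yc, Yc)
        out = np.empty((len(self.positions), Y.shape[1]))
        for k, gp in enumerate(self.positions):
            if gp.valid.all():
                u = gp.basis
                if u.shape[1] == 0:
                    out[k] = 0.0
                    continue
                proj = u.T @ Yc
                rss1 = rss0 - np.einsum("ij,ij->j", proj, proj)
                out[k] = _lod_from_rss(rss0, rss1, n)
            else:
                mask = gp.valid
                m = int(mask.sum())
                if m < 3:
                    out[k] = 0.0
                    continue
                Ys = Y[mask]
                Ysc = Ys - Ys.mean(axis=0)
                r0 = np.einsum("ij,ij->j", Ysc, Ysc)
                d = self._design_columns(gp)[mask]
                dc = d - d.mean(axis=0)
                q, r = np.linalg.qr(dc)
                keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
                u = q[:, keep]
                proj = u.T @ Ysc
                r1 = r0 - np.einsum("ij,ij->j", proj, proj)
                out[k] = _lod_from_rss(r0, r1, m)
        return out[:, 0] if squeeze else out

    def lod_at(self, ks: list[int], y: np.ndarray) -> np.ndarray:
        """LOD for one phenotype at a subset of grid positions."""
        y = np.asarray(y, dtype=float)
        yc = y - y.mean()
        rss0 = float(yc @ yc)
        out = np.empty(len(ks))
        for t, k in enumerate(ks):
            gp = self.positions[k]
            if gp.valid.all():
                u = gp.basis
                if u.shape[1] == 0:
                    out[t] = 0.0
                    continue
                proj = u.T @ yc
                rss1 = rss0 - float(proj @ proj)
                out[t] = _lod_from_rss(np.array([rss0]), np.array([rss1]), self.n_lines)[0]
            else:
                mask = gp.valid
                m = int(mask.sum())
                if m < 3:
                    out[t] = 0.0
                    continue
                ys = y[mask]
                ysc = ys - ys.mean()
                r0 = float(ysc @ ysc)
                d = self._design_columns(gp)[mask]
                dc = d - d.mean(axis=0)
                q, r = np.linalg.qr(dc)
                keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
                u = q[:, keep]
                proj = u.T @ ysc
                out[t] = _lod_from_rss(np.array([r0]), np.array([r0 - float(proj @ proj)]), m)[0]
        return out

    def profile_frame(self, lod: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "linkage_group": [gp.linkage_group for gp in self.positions],
                "pos_cM": [gp.pos_cM for gp in self.positions],
                "left_marker": [gp.left_marker for gp in self.positions],
                "right_marker": [gp.right_marker for gp in self.positions],
                "lod": lod,
            }
        )


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: int) -> np.ndarray:
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.maximum(np.asarray(rss1, dtype=float), rss0 * 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(np.where(rss1 > 0, rss0 / rss1, 1.0))
    lod = np.where(rss0 <= 1e-300, 0.0, lod)
    return np.maximum(lod, 0.0)


def _fit_effects(gp: _GridPosition, y: np.ndarray) -> tuple[float, float, float | None]:
    """(pve, additive, dominance) from the regression at one grid position."""
    mask = gp.valid
    ys = y[mask]
    d = ScanGrid._design_columns(gp)[mask]
    X = np.column_stack([np.ones(len(ys)), d])
    beta, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta
    rss1 = float(resid @ resid)
    yc = ys - ys.mean()
    rss0 = float(yc @ yc)
    pve = 0.0 if rss0 <= 0 else 100.0 * (1.0 - rss1 / rss0)
    additive = float(beta[1])
    dominance = float(beta[2]) if d.shape[1] > 1 else None
    return pve, additive, dominance


def _call_peaks(
    grid: ScanGrid,
    lod: np.ndarray,
    y: np.ndarray,
    gene_id: str,
    method: str,
    lod_threshold: float,
    effect_y: np.ndarray | None = None,
) -> list[EqtlInteraction]:
    """One peak per linkage group: the LOD maximum, if above threshold,
    bounded by its flanking markers."""
    effect_y = y if effect_y is None else effect_y
    groups: dict[str, list[int]] = {}
    for k, gp in enumerate(grid.positions):
        groups.setdefault(gp.linkage_group, []).append(k)
    peaks = []
    for lg_name, idx in groups.items():
        sub = lod[idx]
        k_best = idx[int(np.argmax(sub))]
        if lod[k_best] < lod_threshold or lod[k_best] <= 0:
            continue
        gp = grid.positions[k_best]
        pve, additive, dominance = _fit_effects(gp, effect_y)
        peaks.append(
            EqtlInteraction(
                gene_id=gene_id,
                method=method,
                linkage_group=lg_name,
                chrom=gp.chrom,
                left_bp=gp.left_bp,
                right_bp=gp.right_bp,
                lod=float(lod[k_best]),
                pve=pve,
                additive=additive,
                dominance=dominance,
                peak_cM=gp.pos_cM,
            )
        )
    return peaks


def _as_vector(phenotype, genotypes: GenotypeMatrix) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(genotypes.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    if y.shape != (genotypes.n_lines,):
        raise ValueError("phenotype length does not match the number of lines")
    if np.any(~np.isfinite(y)):
        raise ValueError("phenotype contains missing or non-finite values")
    return y


def im_scan(
    phenotype,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    step_cM: float = 1.0,
    lod_threshold: float = 0.0,
    gene_id: str = "phenotype",
    grid: ScanGrid | None = None,
) -> tuple[ScanProfile, list[EqtlInteraction]]:
    """Interval mapping by Haley-Knott regression.  See module docstring."""
    grid = grid or ScanGrid(gmap, genotypes, step_cM)
    y = _as_vector(phenotype, genotypes)
    lod = grid.lod_matrix(y)
    profile = ScanProfile(gene_id=gene_id, method="IM", table=grid.profile_frame(lod))
    peaks = _call_peaks(grid, lod, y, gene_id, "IM", lod_threshold)
    return profile, peaks


def scan_genes_im(
    expression: pd.DataFrame,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    step_cM: float = 1.0,
    lod_threshold: float = 0.0,
    grid: ScanGrid | None = None,
) -> list[EqtlInteraction]:
    """Vectorized interval-mapping scan over a genes x lines matrix."""
    grid = grid or ScanGrid(gmap, genotypes, step_cM)
    Y = expression[genotypes.line_ids].to_numpy(dtype=float).T  # lines x genes
    lod = grid.lod_matrix(Y)
    peaks: list[EqtlInteraction] = []
    for g, gene in enumerate(expression.index):
        peaks.extend(
            _call_peaks(grid, lod[:, g], Y[:, g], str(gene), "IM", lod_threshold)
        )
    return peaks


# ----------------------------------------------------------------------
# ICIM


def _marker_design(genotypes: GenotypeMatrix) -> np.ndarray:
    """Additive marker codes (A=-1, H=0, B=+1), mean-imputed where missing."""
    x = genotypes.codes.astype(float) - 1.0
    miss = genotypes.codes < 0
    if miss.any():
        col_mean = np.where(
            miss.all(axis=0), 0.0,
            np.nanmean(np.where(miss, np.nan, x), axis=0),
        )
        x = np.where(miss, col_mean[None, :], x)
    return x


def _stepwise_select(
    C: np.ndarray, y: np.ndarray, p_in: float, p_out: float, max_terms: int
) -> list[int]:
    """Forward-backward stepwise marker selection by partial F tests."""
    n, m = C.shape
    sel: list[int] = []
    changed = True
    while changed and len(sel) < max_terms:
        changed = False
        # current fit
        X = np.column_stack([np.ones(n)] + [C[:, j] for j in sel])
        q, _ = np.linalg.qr(X)
        y_res = y - q @ (q.T @ y)
        rss = float(y_res @ y_res)
        if rss <= 1e-12:
            break
        # forward
        cand = [j for j in range(m) if j not in sel]
        if cand:
            Cc = C[:, cand]
            C_res = Cc - q @ (q.T @ Cc)
            norms = np.einsum("ij,ij->j", C_res, C_res)
            ok = norms > 1e-10
            num = np.zeros(len(cand))
            num[ok] = (C_res[:, ok].T @ y_res) ** 2 / norms[ok]
            df = n - len(sel) - 2
            if df > 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fval = num * df / np.maximum(rss - num, 1e-300)
                pvals = stats.f.sf(fval, 1, df)
                pvals[~ok] = 1.0
                best = int(np.argmin(pvals))
                if pvals[best] < p_in:
                    sel.append(cand[best])
                    changed = True
        # backward
        while len(sel) > 1:
            X = np.column_stack([np.ones(n)] + [C[:, j] for j in sel])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = n - X.shape[1]
            if df <= 0:
                break
            s2 = float(resid @ resid) / df
            xtx_inv = np.linalg.pinv(X.T @ X)
            se = np.sqrt(np.maximum(np.diag(xtx_inv) * s2, 1e-300))
            tvals = beta / se
            pvals = 2 * stats.t.sf(np.abs(tvals), df)
            worst = int(np.argmax(pvals[1:])) + 1
            if pvals[worst] > p_out:
                del sel[worst - 1]
                changed = True
            else:
                break
    return sel


def icim_scan(
    phenotype,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    step_cM: float = 1.0,
    p_in: float = 0.001,
    p_out: float = 0.002,
    lod_threshold: float = 0.0,
    gene_id: str = "phenotype",
    grid: ScanGrid | None = None,
    marker_design: np.ndarray | None = None,
) -> tuple[ScanProfile, list[EqtlInteraction]]:
    """Inclusive composite interval mapping.

    Stage 1 selects cofactor markers by stepwise regression at the given
    entry/exit p-values; stage 2 adjusts the phenotype by subtracting the
    fitted contribution of every selected cofactor except the two markers
    flanking the interval currently scanned; stage 3 is interval mapping on
    the adjusted phenotype.  With no cofactors selected the profile equals
    the plain interval-mapping profile exactly.
    """
    grid = grid or ScanGrid(gmap, genotypes, step_cM)
    y = _as_vector(phenotype, genotypes)
    C = _marker_design(genotypes) if marker_design is None else marker_design
    max_terms = max(2, min(genotypes.n_lines // 5, 50))
    sel = _stepwise_select(C, y, p_in, p_out, max_terms)

    if not sel:
        profile, peaks = im_scan(y, gmap, genotypes, step_cM, lod_threshold,
                                 gene_id=gene_id, grid=grid)
        for p in peaks:
            p.method = "ICIM"
        profile.method = "ICIM"
        return profile, peaks

    X = np.column_stack([np.ones(len(y))] + [C[:, j] for j in sel])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    contrib = {j: beta[k + 1] * C[:, j] for k, j in enumerate(sel)}
    marker_col = {m: k for k, m in enumerate(genotypes.marker_ids)}

    # group grid positions by flanking-marker pair; adjust y per interval
    lod = np.zeros(len(grid.positions))
    interval_cache: dict[tuple[str, str], np.ndarray] = {}
    y_adj_by_pos: list[np.ndarray | None] = [None] * len(grid.positions)
    for k, gp in enumerate(grid.positions):
        key = (gp.left_marker, gp.right_marker)
        if key not in interval_cache:
            flank_idx = {marker_col[gp.left_marker], marker_col[gp.right_marker]}
            adj = y - sum(
                (contrib[j] for j in sel if j not in flank_idx),
                np.zeros_like(y),
            )
            interval_cache[key] = adj
        y_adj_by_pos[k] = interval_cache[key]

    # compute LOD per interval block, only at that interval's positions
    interval_positions: dict[tuple[str, str], list[int]] = {}
    for k, gp in enumerate(grid.positions):
        interval_positions.setdefault((gp.left_marker, gp.right_marker), []).append(k)
    for key, ks in interval_positions.items():
        lod[ks] = grid.lod_at(ks, interval_cache[key])

    profile = ScanProfile(gene_id=gene_id, method="ICIM", table=grid.profile_frame(lod))
    # effects are fitted on the interval-adjusted phenotype at the peak
    groups: dict[str, list[int]] = {}
    for k, gp in enumerate(grid.positions):
        groups.setdefault(gp.linkage_group, []).append(k)
    peaks: list[EqtlInteraction] = []
    for lg_name, idx in groups.items():
        sub = lod[idx]
        k_best = idx[int(np.argmax(sub))]
        if lod[k_best] < lod_threshold or lod[k_best] <= 0:
            continue
        gp = grid.positions[k_best]
        pve, additive, dominance = _fit_effects(gp, y_adj_by_pos[k_best])
        peaks.append(
            EqtlInteraction(
                gene_id=gene_id, method="ICIM", linkage_group=lg_name,
                chrom=gp.chrom, left_bp=gp.left_bp, right_bp=gp.right_bp,
                lod=float(lod[k_best]), pve=pve, additive=additive,
                dominance=dominance, peak_cM=gp.pos_cM,
            )
        )
    return profile, peaks


# ----------------------------------------------------------------------
# GCIM stand-in


def _kinship_eig(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the marker-derived kinship (GRM)."""
    Z = _marker_design(genotypes)
    sd = Z.std(axis=0)
    Z = (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    K = Z @ Z.T / Z.shape[1]
    vals, vecs = np.linalg.eigh(K)
    return np.maximum(vals, 0.0), vecs


def _reml_weights(y: np.ndarray, eigvals: np.ndarray, eigvecs: np.ndarray) -> np.ndarray:
    """Per-line whitening weights from a REML fit of the polygenic ratio."""
    n = len(y)
    yt = eigvecs.T @ y
    ones_t = eigvecs.T @ np.ones(n)

    def neg_reml(h2: float) -> float:
        d = h2 * eigvals + (1 - h2)
        w = 1.0 / d
        xtx = float(ones_t @ (w * ones_t))
        beta = float(ones_t @ (w * yt)) / xtx
        r = yt - beta * ones_t
        rss = float(r @ (w * r))
        s2 = rss / (n - 1)
        return (n - 1) * np.log(max(s2, 1e-300)) + np.log(d).sum() + np.log(max(xtx, 1e-300))

    res = optimize.minimize_scalar(neg_reml, bounds=(1e-6, 0.99), method="bounded")
    h2 = float(res.x)
    return 1.0 / np.sqrt(h2 * eigvals + (1 - h2))


def gcim_scan(
    phenotype,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    model: str = "fixed",
    step_cM: float = 1.0,
    top_k: int = 5,
    stage1_lod: float = 2.5,
    lod_threshold: float = 0.0,
    gene_id: str = "phenotype",
    grid: ScanGrid | None = None,
    kinship_eig: tuple[np.ndarray, np.ndarray] | None = None,
    marker_design: np.ndarray | None = None,
) -> list[EqtlInteraction]:
    """Simplified genome-wide composite interval mapping.

    Stage 1 scans the grid with a polygenic control: ``fixed`` regresses on
    top-k marginal cofactor markers (excluding the scanned interval's
    flanks); ``fixed_REML`` fits a variance-component polygenic term with a
    marker-derived kinship by REML and scans on the whitened data.  Per
    linkage group, the LOD maximum passing the liberal stage-1 cut becomes a
    candidate.  Stage 2 refits all candidates jointly with an L1-penalized
    regression; surviving loci are reported with LOD from the joint-model
    likelihood ratio.  With ``top_k=0`` and no polygenic background, stage 1
    is a plain Haley-Knott scan.
    """
    if model not in ("fixed", "fixed_REML"):
        raise ValueError("model must be 'fixed' or 'fixed_REML'")
    grid = grid or ScanGrid(gmap, genotypes, step_cM)
    y = _as_vector(phenotype, genotypes)
    n = len(y)
    C = _marker_design(genotypes) if marker_design is None else marker_design
    marker_col = {m: k for k, m in enumerate(genotypes.marker_ids)}

    weights = None
    if model == "fixed_REML":
        try:
            eigvals, eigvecs = kinship_eig if kinship_eig is not None else _kinship_eig(genotypes)
            weights = _reml_weights(y, eigvals, eigvecs)
            rot = eigvecs.T
        except np.linalg.LinAlgError:
            warnings.warn("kinship eigendecomposition failed; falling back to fixed model",
                          stacklevel=2)
            model = "fixed"

    if model == "fixed_REML":
        y_w = weights * (rot @ y)
        ones_w = weights * (rot @ np.ones(n))

        def position_lod(gp: _GridPosition) -> float:
            d = ScanGrid._design_columns(gp)
            dw = weights[:, None] * (rot @ d)
            X0 = ones_w[:, None]
            X1 = np.column_stack([ones_w, dw])
            return _ols_lod(X0, X1, y_w, n)

    else:
        cofactors: list[int] = []
        if top_k > 0:
            yc = y - y.mean()
            Cc = C - C.mean(axis=0)
            denom = np.sqrt(np.einsum("ij,ij->j", Cc, Cc)) * np.sqrt(yc @ yc)
            with np.errstate(divide="ignore", invalid="ignore"):
                cors = np.abs(Cc.T @ yc) / np.where(denom > 0, denom, np.inf)
            cofactors = list(np.argsort(-cors)[:top_k])

        def position_lod(gp: _GridPosition) -> float:
            flanks = {marker_col[gp.left_marker], marker_col[gp.right_marker]}
            cof = [j for j in cofactors if j not in flanks]
            base = [np.ones(n)] + [C[:, j] for j in cof]
            X0 = np.column_stack(base)
            X1 = np.column_stack(base + [ScanGrid._design_columns(gp)])
            return _ols_lod(X0, X1, y, n)

    # stage 1: per-LG candidate positions above the liberal cut
    lod = np.array([position_lod(gp) for gp in grid.positions])
    groups: dict[str, list[int]] = {}
    for k, gp in enumerate(grid.positions):
        groups.setdefault(gp.linkage_group, []).append(k)
    candidates: list[int] = []
    for idx in groups.values():
        k_best = idx[int(np.argmax(lod[idx]))]
        if lod[k_best] >= stage1_lod:
            candidates.append(k_best)
    if not candidates:
        return []

    # stage 2: penalized joint refit of all candidate positions
    blocks, block_slices = [], []
    start = 0
    for k in candidates:
        d = ScanGrid._design_columns(grid.positions[k])
        blocks.append(d)
        block_slices.append(slice(start, start + d.shape[1]))
        start += d.shape[1]
    D = np.column_stack(blocks)
    mu, sd = D.mean(axis=0), D.std(axis=0)
    Ds = (D - mu) / np.where(sd > 0, sd, 1.0)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Ds.T @ yc)) / n if n else 1.0
    lasso = Lasso(alpha=max(0.05 * alpha_max, 1e-12), fit_intercept=False, max_iter=10000)
    lasso.fit(Ds, yc)
    survive = [
        i for i, sl in enumerate(block_slices)
        if np.any(np.abs(lasso.coef_[sl]) > 1e-8)
    ]
    if not survive:
        return []

    # joint OLS over survivors; per-locus LOD by leaving that locus out
    cols = [np.ones(n)]
    surv_slices = []
    for i in survive:
        sl = block_slices[i]
        surv_slices.append((len(cols), len(cols) + (sl.stop - sl.start)))
        cols.extend(D[:, sl].T)
    Xfull = np.column_stack(cols)
    rss_full = _rss(Xfull, y)
    rss_null = float(((y - y.mean()) ** 2).sum())
    peaks = []
    for (a, b), i in zip(surv_slices, survive):
        k = candidates[i]
        gp = grid.positions[k]
        Xwo = np.delete(Xfull, np.s_[a:b], axis=1)
        rss_wo = _rss(Xwo, y)
        lod_joint = float(_lod_from_rss(np.array([rss_wo]), np.array([rss_full]), n)[0])
        if lod_joint < lod_threshold or lod_joint <= 0:
            continue
        beta, _, _, _ = np.linalg.lstsq(Xfull, y, rcond=None)
        additive = float(beta[a])
        dominance = float(beta[a + 1]) if b - a > 1 else None
        pve = 0.0 if rss_null <= 0 else 100.0 * (rss_wo - rss_full) / rss_null
        peaks.append(
            EqtlInteraction(
                gene_id=gene_id, method="GCIM", linkage_group=gp.linkage_group,
                chrom=gp.chrom, left_bp=gp.left_bp, right_bp=gp.right_bp,
                lod=lod_joint, pve=max(pve, 0.0), additive=additive,
                dominance=dominance if genotypes.population == "F2" else None,
                peak_cM=gp.pos_cM,
            )
        )
    return peaks


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _ols_lod(X0: np.ndarray, X1: np.ndarray, y: np.ndarray, n: int) -> float:
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    return float(_lod_from_rss(np.array([rss0]), np.array([rss1]), n)[0])


# ----------------------------------------------------------------------
# Permutation threshold


@dataclass
class PermutationResult:
    """Pooled genome-wide null maxima and the derived LOD threshold."""

    threshold: float
    null_maxima: np.ndarray
    n_sample_genes: int
    n_perm: int
    alpha: float

    def __float__(self) -> float:
        return self.threshold


def permutation_threshold(
    expression: pd.DataFrame,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    method: str = "IM",
    n_sample_genes: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cM: float = 1.0,
    grid: ScanGrid | None = None,
) -> PermutationResult:
    """Global permutation LOD threshold from sampled transcripts.

    Samples ``n_sample_genes`` genes without replacement; for each, permutes
    the phenotype ``n_perm`` times and records the genome-wide maximum LOD
    per permutation; pools all n_sample_genes x n_perm maxima and returns
    the empirical (1 - alpha) percentile (linear interpolation between order
    statistics).

    Both IM and ICIM use the interval-mapping null kernel: under phenotype
    permutation no marker passes the stepwise entry test, so the ICIM scan
    reduces to plain interval mapping.  GCIM thresholds are fixed by
    configuration, not permutation.
    """
    method = method.upper()
    if method not in ("IM", "ICIM"):
        raise ValueError("permutation thresholds are defined for IM and ICIM")
    if expression.shape[0] < n_sample_genes:
        raise ValueError(
            f"expression has {expression.shape[0]} genes; need >= {n_sample_genes}"
        )
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable percentile estimate", stacklevel=2)

    grid = grid or ScanGrid(gmap, genotypes, step_cM)
    rng = np.random.default_rng(seed)
    gene_idx = rng.choice(expression.shape[0], size=n_sample_genes, replace=False)
    Y = expression[genotypes.line_ids].to_numpy(dtype=float)

    maxima = np.empty(n_sample_genes * n_perm)
    for gi, g in enumerate(gene_idx):
        y = Y[g]
        perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
        lod = grid.lod_matrix(perms)
        maxima[gi * n_perm : (gi + 1) * n_perm] = lod.max(axis=0)

    threshold = float(np.percentile(maxima, 100.0 * (1.0 - alpha)))
    return PermutationResult(
        threshold=threshold, null_maxima=maxima,
        n_sample_genes=n_sample_genes, n_perm=n_perm, alpha=alpha,
    )
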