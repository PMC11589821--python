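"""Scan engines: LOD oracle equality, reductions, recovery, permutations."""

import numpy as np
import pytest

from eqtlcross import (
    HotspotSpec,
    ScanGrid,
    SimulationConfig,
    build_map,
    gcim_scan,
    icim_scan,
    im_scan,
    permutation_threshold,
    scan_genes_im,
    simulate_genotypes,
)


def _marker_lod_oracle(y, codes, population):
    """Closed-form regression LOD at a marker: (n/2) log10(RSS0/RSS1)."""
    n = len(y)
    x = codes.astype(float) - 1.0
    cols = [np.ones(n), x]
    if population == "F2":
        cols.append((codes == 1).astype(float))
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    return n / 2.0 * np.log10(rss0 / rss1)


class TestImScan:
    def test_constant_phenotype_zero_lod_no_peaks(self, f2_cross):
        y = np.ones(f2_cross["genotypes"].n_lines)
        profile, peaks = im_scan(y, f2_cross["gmap"], f2_cross["genotypes"])
        assert np.all(profile.table["lod"] == 0)
        assert peaks == []

    def test_lod_at_marker_equals_regression_oracle(self, exact_map_f2):
        # every marker sits on the grid; LOD there must equal the closed-form
        # regression LOD to 1e-8
        g, grid, gmap = exact_map_f2["genotypes"], exact_map_f2["grid"], exact_map_f2["gmap"]
        rng = np.random.default_rng(11)
        x = g.codes[:, 4].astype(float) - 1
        y = 0.8 * x + rng.normal(size=g.n_lines)
        lod = grid.lod_matrix(y)
        cms = [gp.pos_cM for gp in grid.positions]
        for mk in range(g.n_markers):
            k = cms.index(5.0 * mk)
            oracle = _marker_lod_oracle(y, g.codes[:, mk], "F2")
            assert abs(lod[k] - oracle) < 1e-8

    def test_peak_near_planted_marker_with_effects(self, exact_map_f2):
        g, gmap = exact_map_f2["genotypes"], exact_map_f2["gmap"]
        rng = np.random.default_rng(12)
        codes = g.codes[:, 5]
        x = codes.astype(float) - 1
        z = (codes == 1).astype(float)
        y = 1.0 * x + 0.5 * z + rng.normal(0, 1, size=g.n_lines)
        _, peaks = im_scan(y, gmap, g, lod_threshold=3.0, grid=exact_map_f2["grid"])
        assert len(peaks) == 1
        p = peaks[0]
        true_bp = exact_map_f2["markers"]["pos_bp"].iloc[5]
        assert p.left_bp <= true_bp <= p.right_bp or abs(p.left_bp - true_bp) <= 2_000_000
        assert p.additive == pytest.approx(1.0, abs=0.35)
        assert p.dominance == pytest.approx(0.5, abs=0.6)
        assert 0 <= p.pve <= 100

    def test_ril_peaks_have_no_dominance(self, ril_cross):
        g, gmap, truth = ril_cross["genotypes"], ril_cross["gmap"], ril_cross["truth"]
        reg = truth.hotspot_markers[0]
        x = g.codes[:, g.marker_index(reg["marker_id"])].astype(float) - 1
        y = x + np.random.default_rng(13).normal(size=g.n_lines)
        _, peaks = im_scan(y, gmap, g, lod_threshold=3.0)
        assert peaks and all(p.dominance is None for p in peaks)

    def test_line_reordering_invariance(self, f2_cross):
        from eqtlcross import GenotypeMatrix

        g, gmap = f2_cross["genotypes"], f2_cross["gmap"]
        rng = np.random.default_rng(14)
        y = g.codes[:, 7].astype(float) + rng.normal(size=g.n_lines)
        _, peaks1 = im_scan(y, gmap, g, lod_threshold=2.0)
        perm = rng.permutation(g.n_lines)
        g2 = GenotypeMatrix(
            line_ids=[g.line_ids[i] for i in perm],
            marker_ids=g.marker_ids,
            codes=g.codes[perm],
            population="F2",
        )
        gmap2 = build_map(g2, f2_cross["markers"])
        _, peaks2 = im_scan(y[perm], gmap2, g2, lod_threshold=2.0)
        key = lambda p: (p.linkage_group, p.left_bp, p.right_bp)
        assert sorted(map(key, peaks1)) == sorted(map(key, peaks2))
        assert np.allclose(
            sorted(p.lod for p in peaks1), sorted(p.lod for p in peaks2), atol=1e-8
        )


class TestIcimScan:
    def test_reduces_to_im_without_cofactors(self, f2_cross):
        # entry p-value so strict that nothing is selected
        g, gmap = f2_cross["genotypes"], f2_cross["gmap"]
        y = np.random.default_rng(15).normal(size=g.n_lines)
        prof_icim, _ = icim_scan(y, gmap, g, p_in=1e-300, p_out=2e-300)
        prof_im, _ = im_scan(y, gmap, g)
        assert np.allclose(prof_icim.table["lod"], prof_im.table["lod"], atol=1e-12)

    def test_two_planted_qtl_both_recovered(self):
        # two independent QTL on different chromosomes, effect 1 SD, n=176:
        # both recovered above LOD 4 in >= 90% of 50 seeds
        hits = 0
        for seed in range(50):
            cfg = SimulationConfig(
                population_type="F2", n_lines=176, n_chromosomes=2,
                markers_per_chromosome=20, chromosome_length_bp=40_000_000,
                n_genes=1, cis_fraction=0.0, hotspot_specs=[], seed=1000 + seed,
            )
            g, markers = simulate_genotypes(cfg)
            gmap = build_map(g, markers)
            rng = np.random.default_rng(2000 + seed)
            x1 = g.codes[:, 5].astype(float) - 1
            x2 = g.codes[:, 30].astype(float) - 1
            sd = np.sqrt(x1.var() + x2.var() + 1)
            y = (x1 + x2) * 1.0 + rng.normal(size=176)
            y = y / y.std()
            _, peaks = icim_scan(y, gmap, g, lod_threshold=4.0)
            lgs = {p.linkage_group for p in peaks}
            if {"GM01", "GM02"} <= lgs:
                hits += 1
        assert hits >= 45

    def test_cofactor_adjustment_matches_residual_oracle(self):
        # 5-marker toy: force selection of one strong cofactor and verify the
        # adjusted phenotype used in an interval equals y - beta * cofactor
        cfg = SimulationConfig(
            population_type="F2", n_lines=300, n_chromosomes=1,
            markers_per_chromosome=5, chromosome_length_bp=40_000_000,
            n_genes=1, cis_fraction=0.0, hotspot_specs=[], seed=16,
        )
        g, markers = simulate_genotypes(cfg)
        gmap = build_map(g, markers)
        rng = np.random.default_rng(17)
        x4 = g.codes[:, 4].astype(float) - 1  # strong cofactor at last marker
        y = 2.0 * x4 + rng.normal(0, 0.5, size=300)
        prof, _ = icim_scan(y, gmap, g, p_in=0.001, p_out=0.002)

        # oracle: joint fit on the selected marker, subtract its contribution,
        # then plain Haley-Knott LOD inside the first interval
        from eqtlcross.scan import _marker_design, _stepwise_select

        C = _marker_design(g)
        sel = _stepwise_select(C, y, 0.001, 0.002, 10)
        assert 4 in sel
        X = np.column_stack([np.ones(300)] + [C[:, j] for j in sel])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        y_adj = y - sum(beta[k + 1] * C[:, j] for k, j in enumerate(sel) if j not in (0, 1))
        grid = ScanGrid(gmap, g, 1.0)
        first_interval = [
            k for k, gp in enumerate(grid.positions)
            if (gp.left_marker, gp.right_marker)
            == (g.marker_ids[0], g.marker_ids[1])
        ]
        oracle = grid.lod_at(first_interval, y_adj)
        got = prof.table["lod"].to_numpy()[first_interval]
        assert np.allclose(got, oracle, atol=1e-10)


class TestGcimScan:
    def test_reduces_to_marker_scan_with_no_background(self, exact_map_f2):
        # zero polygenic background and k=0: stage 1 is a plain regression
        # scan, so the reported peak coincides with the IM peak
        g, gmap, grid = exact_map_f2["genotypes"], exact_map_f2["gmap"], exact_map_f2["grid"]
        rng = np.random.default_rng(18)
        y = 1.2 * (g.codes[:, 3].astype(float) - 1) + rng.normal(size=g.n_lines)
        peaks = gcim_scan(y, gmap, g, model="fixed", top_k=0, stage1_lod=0.0,
                          lod_threshold=3.0, grid=grid)
        _, im_peaks = im_scan(y, gmap, g, lod_threshold=3.0, grid=grid)
        assert len(peaks) == 1 and len(im_peaks) == 1
        assert peaks[0].peak_cM == im_peaks[0].peak_cM

    def test_null_false_positive_rate_low(self, f2_cross):
        # null phenotypes: fraction of genes with any call at LOD >= 4 < 10%
        g, gmap = f2_cross["genotypes"], f2_cross["gmap"]
        grid = ScanGrid(gmap, g, 1.0)
        rng = np.random.default_rng(19)
        n_called = 0
        for _ in range(100):
            y = rng.normal(size=g.n_lines)
            peaks = gcim_scan(y, gmap, g, model="fixed", lod_threshold=4.0, grid=grid)
            n_called += bool(peaks)
        assert n_called < 10

    def test_strong_qtl_recovered_both_models(self, f2_cross):
        # enough markers that the kinship is not dominated by the causal one
        g, gmap = f2_cross["genotypes"], f2_cross["gmap"]
        grid = ScanGrid(gmap, g, 1.0)
        true_bp = f2_cross["markers"]["pos_bp"].iloc[6]
        hits = {"fixed": 0, "fixed_REML": 0}
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            y = 1.5 * (g.codes[:, 6].astype(float) - 1) + rng.normal(size=g.n_lines)
            for model in hits:
                peaks = gcim_scan(y, gmap, g, model=model, lod_threshold=4.0, grid=grid)
                hits[model] += any(
                    p.linkage_group == "GM01"
                    and (p.left_bp - 3_000_000 <= true_bp <= p.right_bp + 3_000_000)
                    for p in peaks
                )
        assert hits["fixed"] >= 9 and hits["fixed_REML"] >= 9

    def test_unknown_model_rejected(self, f2_cross):
        with pytest.raises(ValueError, match="model"):
            gcim_scan(np.zeros(176), f2_cross["gmap"], f2_cross["genotypes"],
                      model="random")


class TestPermutationThreshold:
    def test_pool_size_is_genes_times_perms(self, ril_cross):
        counts = ril_cross["counts"]
        from eqtlcross import median_of_ratios_normalize

        norm, _ = median_of_ratios_normalize(counts)
        res = permutation_threshold(
            norm, ril_cross["gmap"], ril_cross["genotypes"],
            n_sample_genes=5, n_perm=120, seed=3,
        )
        assert len(res.null_maxima) == 5 * 120
        assert res.threshold == np.percentile(res.null_maxima, 95)

    def test_reproducible_under_seed(self, ril_cross):
        from eqtlcross import median_of_ratios_normalize

        norm, _ = median_of_ratios_normalize(ril_cross["counts"])
        args = (norm, ril_cross["gmap"], ril_cross["genotypes"])
        r1 = permutation_threshold(*args, n_sample_genes=4, n_perm=100, seed=8)
        r2 = permutation_threshold(*args, n_sample_genes=4, n_perm=100, seed=8)
        assert r1.threshold == r2.threshold
        assert np.array_equal(r1.null_maxima, r2.null_maxima)

    def test_low_n_perm_warns(self, ril_cross):
        from eqtlcross import median_of_ratios_normalize

        norm, _ = median_of_ratios_normalize(ril_cross["counts"])
        with pytest.warns(UserWarning, match="unstable"):
            permutation_threshold(norm, ril_cross["gmap"], ril_cross["genotypes"],
                                  n_sample_genes=2, n_perm=50, seed=1)

    def test_too_few_genes_rejected(self, ril_cross):
        with pytest.raises(ValueError, match="genes"):
            permutation_threshold(
                ril_cross["counts"].iloc[:5], ril_cross["gmap"],
                ril_cross["genotypes"], n_sample_genes=10, n_perm=100,
            )

    def test_gcim_has_no_permutation_threshold(self, ril_cross):
        with pytest.raises(ValueError, match="IM and ICIM"):
            permutation_threshold(ril_cross["counts"], ril_cross["gmap"],
                                  ril_cross["genotypes"], method="GCIM")


class TestScanGenesVectorized:
    def test_matrix_scan_agrees_with_single_gene_scan(self, ril_cross):
        from eqtlcross import median_of_ratios_normalize

        norm, _ = median_of_ratios_normalize(ril_cross["counts"])
        sub = norm.iloc[:10]
        g, gmap = ril_cross["genotypes"], ril_cross["gmap"]
        peaks_mat = scan_genes_im(sub, gmap, g, lod_threshold=3.0)
        peaks_one = []
        for gene in sub.index:
            _, p = im_scan(sub.loc[gene], gmap, g, lod_threshold=3.0, gene_id=str(gene))
            peaks_one.extend(p)
        key = lambda p: (p.gene_id, p.linkage_group, p.left_bp)
        assert sorted(map(key, peaks_mat)) == sorted(map(key, peaks_one))
        assert np.allclose(
            sorted(p.lod for p in peaks_mat), sorted(p.lod for p in peaks_one),
            atol=1e-10,
        )
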