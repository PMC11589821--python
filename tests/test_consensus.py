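"""Cis/trans classification, region padding, >=2-method consensus merge."""

import numpy as np
import pandas as pd
import pytest

from eqtlcross import (
    EqtlInteraction,
    classify_all,
    classify_cis_trans,
    codify,
    expand_region,
    merge_methods,
    parse_codification,
)


def _it(gene="g1", method="IM", chrom="GM01", left=1_000_000, right=1_100_000,
        regulation=None, lod=5.0):
    return EqtlInteraction(
        gene_id=gene, method=method, linkage_group=chrom.replace("GM", ""),
        chrom=chrom, left_bp=left, right_bp=right, lod=lod, pve=10.0,
        additive=1.0, dominance=None, regulation=regulation,
    )


def _ann(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_bp", "strand"])


class TestClassify:
    def test_other_chromosome_is_trans(self):
        ann = _ann([("g1", "GM02", 500_000, "+")])
        assert classify_cis_trans(_it(chrom="GM01"), ann) == "trans"

    def test_distance_arithmetic_within_window(self):
        # TSS 41,900,000 vs region 41,500,000-41,600,000: distance 300,000 -> cis
        ann = _ann([("g1", "GM01", 41_900_000, "+")])
        it = _it(left=41_500_000, right=41_600_000)
        assert classify_cis_trans(it, ann) == "cis"

    def test_boundary_exactly_window_is_cis(self):
        ann = _ann([("g1", "GM01", 3_000_000, "+")])
        assert classify_cis_trans(_it(left=4_000_000, right=4_100_000), ann) == "cis"
        assert classify_cis_trans(_it(left=4_000_001, right=4_100_000), ann) == "trans"

    def test_tss_inside_region_is_cis(self):
        ann = _ann([("g1", "GM01", 1_050_000, "+")])
        assert classify_cis_trans(_it(), ann) == "cis"

    def test_unannotated_gene_error_names_gene(self):
        ann = _ann([("other", "GM01", 1, "+")])
        with pytest.raises(KeyError, match="g1"):
            classify_cis_trans(_it(), ann)

    def test_distant_same_chromosome_trans_like_table3(self):
        # a gene on one chromosome regulated from a far region: trans
        ann = _ann([("GmPRR1a", "GM04", 41_900_000, "+")])
        it = _it(gene="GmPRR1a", chrom="GM15", left=49_442_075, right=49_442_237)
        assert classify_cis_trans(it, ann) == "trans"


class TestExpandRegion:
    def test_plain_padding(self):
        assert expand_region(2_000_000, 2_100_000, 500_000, 10_000_000) == (
            1_500_000, 2_600_000,
        )

    def test_clamps_to_one(self):
        assert expand_region(100_000, 200_000, 500_000, 10_000_000)[0] == 1

    def test_clamps_to_chromosome_length(self):
        assert expand_region(9_800_000, 9_900_000, 500_000, 10_000_000)[1] == 10_000_000

    def test_padded_point_regions_touch_within_1mbp(self):
        # two point regions 999,999 bp apart overlap after +/-500 kb padding;
        # 1,000,001 bp apart do not
        a = expand_region(2_000_000, 2_000_000)
        b = expand_region(2_999_999, 2_999_999)
        assert a[0] <= b[1] and b[0] <= a[1]
        c = expand_region(3_000_001, 3_000_001)
        assert not (a[0] <= c[1] and c[0] <= a[1])


class TestMergeMethods:
    def test_identical_interaction_three_methods_one_region(self):
        by_method = {
            m: [_it(method=m, regulation="trans")] for m in ("ICIM", "IM", "GCIM")
        }
        regions = merge_methods(by_method)
        assert len(regions) == 1
        assert regions[0].methods == frozenset({"ICIM", "IM", "GCIM"})
        assert (regions[0].start_bp, regions[0].end_bp) == (1_000_000, 1_100_000)

    def test_single_method_signal_dropped(self):
        by_method = {
            "ICIM": [_it(method="ICIM", regulation="trans")],
            "IM": [_it(method="IM", chrom="GM05", regulation="trans")],
        }
        assert merge_methods(by_method) == []

    def test_fewer_than_two_methods_error(self):
        with pytest.raises(ValueError, match="2 methods"):
            merge_methods({"IM": [_it(regulation="trans")]})

    def test_unclassified_interaction_rejected(self):
        with pytest.raises(ValueError, match="cis/trans"):
            merge_methods({"IM": [_it()], "ICIM": [_it(method="ICIM")]})

    def test_union_coordinates_unpadded(self):
        by_method = {
            "ICIM": [_it(method="ICIM", left=1_000_000, right=1_200_000,
                         regulation="trans")],
            "IM": [_it(method="IM", left=1_900_000, right=2_000_000,
                       regulation="trans")],
        }
        (region,) = merge_methods(by_method)
        assert (region.start_bp, region.end_bp) == (1_000_000, 2_000_000)

    def test_trans_overlapping_cis_reclassified(self):
        # the gene has a cis consensus region; a trans consensus region of the
        # same gene within padded reach becomes cis ("de facto")
        ann = _ann([("g1", "GM01", 1_050_000, "+")])
        cis_a = _it(method="ICIM", left=1_000_000, right=1_100_000)
        cis_b = _it(method="IM", left=1_000_000, right=1_100_000)
        # > 1 Mbp from the TSS (hence trans) but within 1 Mbp of the cis region
        trans_a = _it(method="ICIM", left=2_060_000, right=2_160_000)
        trans_b = _it(method="IM", left=2_060_000, right=2_160_000)
        by_method = {"ICIM": [cis_a, trans_a], "IM": [cis_b, trans_b]}
        for lst in by_method.values():
            classify_all(lst, ann)
        assert trans_a.regulation == "trans"
        regions = merge_methods(by_method)
        assert len(regions) == 2
        assert all(r.regulation == "cis" for r in regions)

    def test_matches_bruteforce_all_pairs_oracle(self):
        # 10 random interactions across 3 methods vs an independently coded
        # repeated-merge enumeration
        rng = np.random.default_rng(23)
        pool = []
        for i in range(10):
            m = ("ICIM", "IM", "GCIM")[i % 3]
            left = int(rng.integers(1, 30) * 100_000)
            pool.append(
                _it(
                    gene=rng.choice(["gA", "gB"]),
                    method=m,
                    chrom=rng.choice(["GM01", "GM02"]),
                    left=left,
                    right=left + int(rng.integers(1, 5) * 100_000),
                    regulation="trans",
                )
            )
        by_method = {}
        for it in pool:
            by_method.setdefault(it.method, []).append(it)
        regions = merge_methods(by_method)

        # oracle: repeatedly merge any two clusters from different methods
        # whose padded hulls of members intersect (same gene, same chrom)
        def overlaps(a, b):
            return (
                a.gene_id == b.gene_id
                and a.chrom == b.chrom
                and a.left_bp - 500_000 <= b.right_bp + 500_000
                and b.left_bp - 500_000 <= a.right_bp + 500_000
            )

        clusters = [{i} for i in range(len(pool))]
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(
                        overlaps(pool[a], pool[b])
                        and pool[a].method != pool[b].method
                        for a in clusters[i]
                        for b in clusters[j]
                    ):
                        clusters[i] |= clusters[j]
                        del clusters[j]
                        changed = True
                        break
                if changed:
                    break
        expected = set()
        for c in clusters:
            methods = {pool[i].method for i in c}
            if len(methods) >= 2:
                expected.add(
                    (
                        pool[next(iter(c))].gene_id,
                        pool[next(iter(c))].chrom,
                        min(pool[i].left_bp for i in c),
                        max(pool[i].right_bp for i in c),
                        frozenset(methods),
                    )
                )
        got = {
            (r.gene_id, r.chrom, r.start_bp, r.end_bp, r.methods) for r in regions
        }
        assert got == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(29)
        pool = [
            _it(gene="g1", method=m, left=int(l), right=int(l) + 50_000,
                regulation="trans")
            for m, l in zip(
                ["ICIM", "IM", "GCIM", "ICIM", "IM"],
                rng.integers(1, 5_000_000, size=5),
            )
        ]
        by1 = {}
        for it in pool:
            by1.setdefault(it.method, []).append(it)
        by2 = {m: list(reversed(lst)) for m, lst in by1.items()}
        key = lambda r: (r.gene_id, r.chrom, r.start_bp, r.end_bp, tuple(sorted(r.methods)))
        assert sorted(map(key, merge_methods(by1))) == sorted(map(key, merge_methods(by2)))

    def test_unique_regions_at_most_pairwise_total(self):
        # Table-1 structure: duplicates across the three pairwise comparisons
        # collapse, so unique count <= sum over pairwise comparisons
        by_method = {
            m: [_it(method=m, regulation="trans"),
                _it(method=m, gene="g2", chrom="GM03", left=7_000_000,
                    right=7_050_000, regulation="trans")]
            for m in ("ICIM", "IM", "GCIM")
        }
        unique = len(merge_methods(by_method))
        pairwise_total = sum(
            len(merge_methods({a: by_method[a], b: by_method[b]}))
            for a, b in (("ICIM", "IM"), ("ICIM", "GCIM"), ("IM", "GCIM"))
        )
        assert unique == 2
        assert unique <= pairwise_total


class TestCodification:
    def test_paper_example_parses_and_roundtrips(self):
        text = "trans_Glyma.01G123600_GM05 40000 200000"
        parsed = parse_codification(text)
        assert parsed == ("trans", "Glyma.01G123600", "GM05", 40_000, 200_000)
        assert codify(*parsed) == text

    def test_gene_names_with_underscores_survive(self):
        text = codify("cis", "gene_with_underscores", "GM10", 1, 2)
        assert parse_codification(text) == ("cis", "gene_with_underscores", "GM10", 1, 2)

    def test_bad_class_rejected(self):
        with pytest.raises(ValueError):
            parse_codification("both_g1_GM01 1 2")
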