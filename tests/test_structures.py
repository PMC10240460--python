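"""Catalog merging, hotspots, density stretches, structures and blocks."""

import numpy as np
import pytest

from breedsig import ThresholdConfig
from breedsig.engine import BSGSRecord, Orientation, SignatureRecord, VariantType
from breedsig.io import EffectAnnotation, chrom_sort_key
from breedsig.structures import (
    SegmentRecord,
    blocks_with_at_least,
    find_breed_structures,
    find_density_stretches,
    find_gene_hotspots,
    merge_bsgs_catalogs,
    par_summary,
    stretches_for_catalog,
    summarize_blocks,
)

CFG = ThresholdConfig()


def bsgs(chrom, pos, breed="Akita", vtype=VariantType.SNP, gene="", term="", functional=False):
    ann = ()
    if gene or term:
        ann = (
            EffectAnnotation(
                allele="G", effect_term=term or "intron_variant",
                gene_label=gene, region_label=gene,
            ),
        )
    return BSGSRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        variant_type=vtype,
        orientation=Orientation.VARIANT,
        carrier_breeds=frozenset({breed}),
        n_reference_solid=300,
        annotations=ann,
        is_functional=functional,
    )


def gs(chrom, pos, carriers):
    return SignatureRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        variant_type=VariantType.SNP,
        orientation=Orientation.VARIANT,
        carrier_breeds=frozenset(carriers),
        n_reference_solid=300,
    )


class TestMerge:
    def test_three_way_merge_sorted(self):
        snp = [bsgs("chr1", p) for p in (10, 30, 50)]
        indel = [bsgs("chr1", p, vtype=VariantType.INDEL) for p in (20, 60)]
        strs = [bsgs("chr2", 5, vtype=VariantType.STR)]
        cat = merge_bsgs_catalogs(snp, indel, strs)
        assert len(cat) == 6
        assert [(e.chrom, e.pos) for e in cat.entries] == [
            ("chr1", 10), ("chr1", 20), ("chr1", 30), ("chr1", 50),
            ("chr1", 60), ("chr2", 5),
        ]

    def test_same_coordinate_fused_into_multitype_entry(self):
        snp = [bsgs("chr1", 100)]
        strs = [bsgs("chr1", 100, vtype=VariantType.STR)]
        cat = merge_bsgs_catalogs(snp, [], strs)
        assert len(cat) == 1
        assert cat.entries[0].types == (VariantType.SNP, VariantType.STR)
        assert cat.n_records == 2  # counts conserved

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="not coordinate-sorted"):
            merge_bsgs_catalogs([bsgs("chr1", 50), bsgs("chr1", 10)], [], [])

    def test_matches_concatenate_and_sort_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lists = []
            for vtype in VariantType:
                pos = np.sort(rng.choice(10_000, size=rng.integers(0, 30), replace=False))
                lists.append([bsgs("chr1", int(p), vtype=vtype) for p in pos])
            cat = merge_bsgs_catalogs(*lists)
            flat = [r for e in cat.entries for r in e.records]
            oracle = sorted(
                lists[0] + lists[1] + lists[2],
                key=lambda r: (chrom_sort_key(r.chrom), r.pos),
            )
            assert [(r.chrom, r.pos) for r in flat] == [
                (r.chrom, r.pos) for r in oracle
            ]


class TestHotspots:
    def test_boundary_at_five(self):
        five = [bsgs("chr1", 100 + i, gene="NKAIN3") for i in range(5)]
        cat = merge_bsgs_catalogs(five, [], [])
        (h,) = find_gene_hotspots(cat, CFG)
        assert h.region_label == "NKAIN3" and h.n_total == 5
        four = merge_bsgs_catalogs(five[:4], [], [])
        assert find_gene_hotspots(four, CFG) == []

    def test_large_single_gene_cluster_counts_once(self):
        many = [bsgs("chr1", 1000 + i * 300, gene="NKAIN3", breed="BullTerrier")
                for i in range(102)]
        cat = merge_bsgs_catalogs(many, [], [])
        (h,) = find_gene_hotspots(cat, CFG)
        assert h.breed == "BullTerrier" and h.n_total == 102

    def test_missing_label_warns(self):
        five = [bsgs("chr1", 100 + i) for i in range(5)]
        cat = merge_bsgs_catalogs(five, [], [])
        with pytest.warns(UserWarning, match="unannotated"):
            (h,) = find_gene_hotspots(cat, CFG)
        assert h.region_label == "unannotated"


def oracle_stretches(positions, cfg):
    """Exhaustive enumeration of qualifying windows reduced to maximal ones,
    coalescing overlaps by the longest qualifying stretch."""
    n = len(positions)

    def ok(i, j):
        c = j - i + 1
        if c < cfg.stretch_min:
            return False
        span = positions[j] - positions[i]
        return span == 0 or c / (span / 1000.0) >= cfg.stretch_density

    qual = {(i, j) for i in range(n) for j in range(i, n) if ok(i, j)}
    maximal = sorted(
        (i, j)
        for (i, j) in qual
        if (i - 1, j) not in qual and (i, j + 1) not in qual
    )
    clusters, current = [], []
    for w in maximal:
        if current and w[0] <= current[-1][1]:
            current.append(w)
        else:
            if current:
                clusters.append(current)
            current = [w]
    if current:
        clusters.append(current)
    out = []
    for cl in clusters:
        best = max(
            cl,
            key=lambda w: (positions[w[1]] - positions[w[0]], w[1] - w[0], -w[0]),
        )
        out.append((positions[best[0]], positions[best[1]], best[1] - best[0] + 1))
    return out


class TestStretches:
    def test_published_airedale_stretch_arithmetic(self):
        """13 members spanning 50532539-50533705 -> 1.17 kb at 11.15/kb."""
        inner = np.linspace(50532539, 50533705, 13).astype(int).tolist()
        inner[0], inner[-1] = 50532539, 50533705
        (seg,) = find_density_stretches(inner, CFG, breed="AiredaleTerrier", chrom="chr17")
        assert (seg.start, seg.end, seg.n_total) == (50532539, 50533705, 13)
        assert f"{seg.length_kb:.2f}" == "1.17"
        assert f"{seg.density:.2f}" == "11.15"

    def test_density_below_cutoff_reports_nothing(self):
        positions = np.linspace(2000, 4000, 10).astype(int).tolist()
        assert find_density_stretches(positions, CFG) == []

    def test_too_few_members_reports_nothing(self):
        assert find_density_stretches([100, 110, 120], CFG) == []

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(0, 50))
            positions = sorted(rng.integers(0, 5_000, size=n).tolist())
            got = [
                (s.start, s.end, s.n_total)
                for s in find_density_stretches(positions, CFG)
            ]
            assert got == oracle_stretches(positions, CFG)

    def test_reported_stretches_satisfy_their_predicate(self, catalogs, cfg):
        cat = merge_bsgs_catalogs(
            catalogs.bsgs_snp, catalogs.bsgs_indel, catalogs.bsgs_str
        )
        stretches = stretches_for_catalog(cat, cfg)
        assert stretches, "synthetic cohort plants one dense stretch"
        for s in stretches:
            assert s.n_total >= cfg.stretch_min
            assert s.density >= cfg.stretch_density


class TestStructures:
    def test_published_akita_structure_arithmetic(self):
        """204 members (180 SNP + 23 INDEL + 1 STR) spanning
        chr17:1900616-2086392 -> 185.78 kb at 1.10/kb."""
        start, end = 1_900_616, 2_086_392
        pos = np.linspace(start, end, 204).astype(int).tolist()
        pos[0], pos[-1] = start, end
        types = [VariantType.SNP] * 180 + [VariantType.INDEL] * 23 + [VariantType.STR]
        records = sorted(
            (bsgs("chr17", p, vtype=t) for p, t in zip(pos, types)),
            key=lambda r: r.pos,
        )
        cat = merge_bsgs_catalogs(
            sorted((r for r in records if r.variant_type is VariantType.SNP), key=lambda r: r.pos),
            sorted((r for r in records if r.variant_type is VariantType.INDEL), key=lambda r: r.pos),
            sorted((r for r in records if r.variant_type is VariantType.STR), key=lambda r: r.pos),
        )
        (seg,) = find_breed_structures(cat, CFG)
        assert (seg.start, seg.end, seg.n_total) == (start, end, 204)
        assert f"{seg.length_kb:.2f}" == "185.78"
        assert f"{seg.density:.2f}" == "1.10"

    def test_gap_split_drops_small_runs(self):
        a = [bsgs("chr1", 1000 + i * 10) for i in range(6)]
        b = [bsgs("chr1", 1_000_000 + i * 10) for i in range(6)]
        cat = merge_bsgs_catalogs(a + b, [], [])
        assert find_breed_structures(cat, CFG) == []

    def test_gap_rule_is_inclusive_at_100kb(self):
        members = [bsgs("chr1", 1 + i * 100_000) for i in range(10)]
        cat = merge_bsgs_catalogs(members, [], [])
        (seg,) = find_breed_structures(cat, CFG)
        assert seg.n_total == 10
        over = [bsgs("chr1", 1 + i * 100_001) for i in range(10)]
        assert find_breed_structures(merge_bsgs_catalogs(over, [], []), CFG) == []

    def test_functional_flags_propagate(self, catalogs, cfg):
        cat = merge_bsgs_catalogs(
            catalogs.bsgs_snp, catalogs.bsgs_indel, catalogs.bsgs_str
        )
        structures = find_breed_structures(cat, cfg)
        functional = [s for s in structures if s.is_functional]
        assert any("OTOGL" in s.functional_genes for s in functional)
        for s in structures:
            assert s.n_total >= cfg.structure_min


class TestBlocks:
    def test_block_boundary_convention(self):
        blocks = summarize_blocks(
            [gs("chr1", 10_000, {"A"}), gs("chr1", 10_001, {"A"})], CFG
        )
        assert [(b.block, b.n_gs) for b in blocks] == [(0, 1), (1, 1)]

    def test_mean_breeds_per_gs(self):
        carriers3 = {f"b{i}" for i in range(3)}
        carriers13 = {f"b{i}" for i in range(13)}
        (b,) = summarize_blocks(
            [gs("chr1", 100, carriers3), gs("chr1", 200, carriers13)], CFG
        )
        assert b.mean_breeds_per_gs == 8.0

    def test_counts_conserved_on_cohort(self, catalogs, cfg):
        blocks = summarize_blocks(catalogs.gs, cfg)
        assert sum(b.n_gs for b in blocks) == len(catalogs.gs)
        assert blocks_with_at_least(blocks, 0) == blocks


class TestPAR:
    def test_block_after_par_end_excluded(self):
        records = [gs("chrX", 6_600_001, {"A", "B", "C"})]
        blocks = summarize_blocks(records, CFG)
        summary = par_summary(blocks, records, CFG)
        assert summary["n_gs"] == 0

    def test_empty_par(self):
        with pytest.warns(UserWarning, match="PAR"):
            summary = par_summary([], [], CFG)
        assert summary["n_gs"] == 0

    def test_planted_par_enrichment_recovered(self, catalogs, cfg):
        blocks = summarize_blocks(catalogs.gs, cfg)
        summary = par_summary(blocks, catalogs.gs, cfg)
        # the cohort plants two PAR blocks with > 40 signatures (45 and 50)
        assert summary["n_high_blocks"] == 2
        assert summary["n_gs_in_high_blocks"] == 95
        assert summary["n_gs"] == 127
        assert summary["fraction_in_high_blocks"] == pytest.approx(95 / 127)
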