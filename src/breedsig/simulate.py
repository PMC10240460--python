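"""Deterministic multi-breed cohort simulator with planted ground truth.

The generator emulates the statistical structure the discovery definitions
respond to — within-breed fixation, cross-breed exclusivity, bimodal STR
repeat counts, positional clustering (dense stretches, gene hotspots,
multi-type structures, PAR enrichment on X) and noisy per-sample depths —
without any demographic realism.  Every planted feature is recorded in a
truth table stating exactly which catalogs it must (or must not) appear in;
near-miss decoys are constructed to fail exactly one discovery rule each
(carrier frequency, breed validity via depth, or reference support).

Background loci are built so that *no* subset of solid calls can push any
breed's BVF to the carrier threshold: every breed holds exactly two hom-ref,
two hom-alt and one het dog (or the analogous 2 low / 2 high / 1 mixed STR
pattern), so at most two of any three or more solid dogs agree.  This makes
planted-truth precision exactly checkable under arbitrary depth dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig

__all__ = ["CohortDesign", "simulate_cohort", "plant_str_locus", "default_breeds"]


def default_breeds() -> dict[str, int]:
    return {
        "Akita": 5,
        "AlaskanMalamute": 5,
        "ChowChow": 5,
        "SussexSpaniel": 5,
        "Collie": 5,
        "Boxer": 5,
        "Keeshond": 5,
        "Samoyed": 5,
    }


@dataclass
class CohortDesign:
    """Desk-scale cohort layout: 8 breeds x 5 dogs, two autosomes plus X.

    ``depth_mean``/``depth_min`` bound the per-sample read depth draw for
    well-covered calls; ``dropout_rate`` is the fraction of background calls
    whose depth falls below the solid-call threshold.
    """

    breeds: dict = field(default_factory=default_breeds)
    chrom_lengths: dict = field(
        default_factory=lambda: {
            "chr1": 5_000_000,
            "chr2": 5_000_000,
            "chrX": 8_000_000,
        }
    )
    n_background: dict = field(
        default_factory=lambda: {"chr1": 1600, "chr2": 1600, "chrX": 1300}
    )
    depth_min: int = 12
    depth_min_x: int = 6
    depth_mean: int = 30
    dropout_rate: float = 0.03

    @classmethod
    def from_file(cls, path) -> "CohortDesign":
        """Flat key=value overrides for the numeric design fields."""
        design = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in {f.name for f in fields(cls)}:
                raise KeyError(f"{path}:{lineno}: unknown design key {key!r}")
            current = getattr(design, key)
            if isinstance(current, dict):
                raise ValueError(f"{path}:{lineno}: {key} not overridable")
            setattr(
                design,
                key,
                float(value) if isinstance(current, float) else int(value),
            )
        return design

    @property
    def samples(self) -> list[str]:
        return [
            f"{breed}_{i + 1}"
            for breed in self.breeds
            for i in range(self.breeds[breed])
        ]

    @property
    def breed_names(self) -> list[str]:
        return list(self.breeds)


# genotype codes for bi-allelic loci
RR, RA, AA = (0, 0), (0, 1), (1, 1)

# mixture pattern for a breed that must never reach carrier frequency in any
# orientation, under any depth dropout: 2 hom-ref / 2 hom-alt / 1 het
SAFE_PATTERN = [RR, RR, AA, AA, RA]
# mirrored pattern for loci whose planted orientation is REFERENCE
ALT_HEAVY_PATTERN = [RA, RA, AA, AA, AA]
REF_HEAVY_PATTERN = [RA, RA, RR, RR, RR]


@dataclass
class _Locus:
    chrom: str
    pos: int
    ref: str
    alts: tuple
    gts: list  # per-sample (a, b)
    ann: Optional[str] = None
    depth_override: dict = field(default_factory=dict)  # sample index -> depth
    background: bool = False  # dropout allowed
    truth: Optional[dict] = None


def _ann_entry(
    allele: str,
    term: str,
    gene: str,
    protein_change: str = "",
) -> str:
    sub = [""] * 15
    sub[0] = allele
    sub[1] = term
    sub[2] = "MODIFIER"
    sub[3] = gene
    sub[4] = gene
    sub[5] = "transcript"
    sub[6] = "t1"
    sub[7] = "protein_coding"
    sub[13] = protein_change
    return "|".join(sub)


def plant_str_locus(
    unit: str,
    carrier_counts: Sequence[int],
    other_counts: Sequence[int],
    anchor: str = "A",
) -> tuple[str, tuple, dict]:
    """Build the VCF allele set of a planted STR locus.

    Alleles are ``anchor + unit*k`` for every distinct repeat count; the
    lowest-count allele becomes REF.  Returns (ref, alts, count->allele-index
    map).  Count groups must not overlap and must differ by >= 1 unit.
    """
    counts = sorted(set(carrier_counts) | set(other_counts))
    if set(carrier_counts) & set(other_counts):
        raise ValueError("carrier and reference repeat groups overlap")
    if len(counts) < 3:
        raise ValueError("an STR locus needs at least three distinct alleles")
    alleles = {k: anchor + unit * k for k in counts}
    if len(set(alleles.values())) != len(alleles):
        raise ValueError("overlapping allele strings in STR design")
    ref = alleles[counts[0]]
    alts = tuple(alleles[k] for k in counts[1:])
    index = {k: i for i, k in enumerate(counts)}
    return ref, alts, index


def _truth(
    chrom,
    pos,
    kind,
    variant_type,
    orientation,
    carriers,
    expect_gs,
    expect_bsgs,
    expect_pair=False,
    str_signature_type="",
    unit_diff=0,
    cluster="",
    gene="",
    effect_term="",
    decoy_rule="",
) -> dict:
    return {
        "chrom": chrom,
        "pos": pos,
        "kind": kind,
        "variant_type": variant_type,
        "orientation": orientation,
        "carriers": ",".join(carriers),
        "expect_gs": expect_gs,
        "expect_bsgs": expect_bsgs,
        "expect_pair": expect_pair,
        "str_signature_type": str_signature_type,
        "unit_diff": unit_diff,
        "cluster": cluster,
        "gene": gene,
        "effect_term": effect_term,
        "decoy_rule": decoy_rule,
    }


class _Builder:
    def __init__(self, design: CohortDesign, rng: np.random.Generator):
        self.design = design
        self.rng = rng
        self.samples = design.samples
        self.breed_slices: dict[str, slice] = {}
        offset = 0
        for breed, n in design.breeds.items():
            self.breed_slices[breed] = slice(offset, offset + n)
            offset += n
        self.loci: list[_Locus] = []

    # -- genotype helpers --------------------------------------------------

    def _assign(self, gts, breed, pattern):
        sl = self.breed_slices[breed]
        n = sl.stop - sl.start
        perm = self.rng.permutation(n)
        for k, i in enumerate(range(sl.start, sl.stop)):
            gts[i] = pattern[perm[k] % len(pattern)]

    def _biallelic_gts(
        self,
        carriers: Sequence[str],
        carrier_code,
        other_pattern,
    ) -> list:
        gts = [None] * len(self.samples)
        for breed in self.design.breeds:
            if breed in carriers:
                sl = self.breed_slices[breed]
                for i in range(sl.start, sl.stop):
                    gts[i] = carrier_code
            else:
                self._assign(gts, breed, other_pattern)
        return gts

    # -- planting ----------------------------------------------------------

    def add_biallelic(
        self,
        chrom,
        pos,
        carriers,
        *,
        kind,
        ref="A",
        alt="G",
        orientation="VARIANT",
        expect_gs=True,
        expect_bsgs=False,
        expect_pair=False,
        gene="",
        effect_term="",
        protein_change="",
        cluster="",
        decoy_rule="",
        depth_override=None,
        carrier_override_code=None,
    ):
        variant_type = (
            "SNP" if len(ref) == 1 and len(alt) == 1 else "INDEL"
        )
        if orientation == "VARIANT":
            carrier_code, other_pattern = AA, REF_HEAVY_PATTERN
        else:
            carrier_code, other_pattern = RR, ALT_HEAVY_PATTERN
        if carrier_override_code is not None:
            carrier_code = carrier_override_code
        gts = self._biallelic_gts(carriers, carrier_code, other_pattern)
        if carrier_override_code == "ONE_HET":  # frequency decoy
            sl = self.breed_slices[carriers[0]]
            for i in range(sl.start, sl.stop):
                gts[i] = AA
            gts[sl.stop - 1] = RA
        # every planted site carries an annotation; unlabelled ones get a
        # synthetic intronic LOC so hotspot grouping stays well defined
        ann_term = effect_term or "intron_variant"
        ann_gene = gene or f"LOC{100000 + pos % 900000}"
        ann = _ann_entry(alt, ann_term, ann_gene, protein_change)
        self.loci.append(
            _Locus(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                gts=gts,
                ann=ann,
                depth_override=depth_override or {},
                truth=_truth(
                    chrom,
                    pos,
                    kind,
                    variant_type,
                    orientation,
                    carriers,
                    expect_gs,
                    expect_bsgs,
                    expect_pair,
                    cluster=cluster,
                    gene=gene,
                    effect_term=effect_term,
                    decoy_rule=decoy_rule,
                ),
            )
        )

    def add_str(
        self,
        chrom,
        pos,
        carrier,
        *,
        unit,
        carrier_counts,
        other_counts,
        anchor="A",
        signature_type,
        expect_bsgs=True,
        kind=None,
        gene="",
        effect_term="",
        cluster="",
        decoy_rule="",
        carrier_mixed_dog=False,
    ):
        ref, alts, index = plant_str_locus(
            unit, carrier_counts, other_counts, anchor=anchor
        )
        carrier_alleles = [index[k] for k in sorted(carrier_counts)]
        other_alleles = [index[k] for k in sorted(other_counts)]
        gts = [None] * len(self.samples)
        for breed in self.design.breeds:
            sl = self.breed_slices[breed]
            idx = list(range(sl.start, sl.stop))
            if breed == carrier:
                for j, i in enumerate(idx):
                    a = carrier_alleles[j % len(carrier_alleles)]
                    gts[i] = (a, a)
                if carrier_mixed_dog:
                    gts[idx[-1]] = (carrier_alleles[0], other_alleles[0])
            else:
                for j, i in enumerate(idx[:-1]):
                    a = other_alleles[j % len(other_alleles)]
                    gts[i] = (a, a)
                gts[idx[-1]] = (other_alleles[0], carrier_alleles[0])
        # repeat-count gap between the groups: min(high) - max(low)
        if min(carrier_counts) > max(other_counts):
            unit_diff = min(carrier_counts) - max(other_counts)
        else:
            unit_diff = min(other_counts) - max(carrier_counts)
        ann = _ann_entry(
            alts[0],
            effect_term or "intron_variant",
            gene or f"LOC{100000 + pos % 900000}",
        )
        expect = expect_bsgs and not carrier_mixed_dog
        self.loci.append(
            _Locus(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                gts=gts,
                ann=ann,
                truth=_truth(
                    chrom,
                    pos,
                    kind or f"BSGS_STR_{signature_type}",
                    "STR",
                    "STR_HIGH" if signature_type == "EXPANSION" else "STR_LOW",
                    (carrier,),
                    expect_gs=expect,
                    expect_bsgs=expect,
                    str_signature_type=signature_type if expect else "",
                    unit_diff=unit_diff,
                    cluster=cluster,
                    gene=gene,
                    effect_term=effect_term,
                    decoy_rule=decoy_rule,
                ),
            )
        )

    def add_background(self, chrom, pos):
        r = self.rng.random()
        gts = [None] * len(self.samples)
        if r < 0.85:  # SNP
            ref, alts = "A", ("G",)
            for breed in self.design.breeds:
                self._assign(gts, breed, SAFE_PATTERN)
        elif r < 0.93:  # bi-allelic INDEL
            ref, alts = "A", ("A" + "TG"[int(self.rng.integers(2))] * int(self.rng.integers(1, 5)),)
            for breed in self.design.breeds:
                self._assign(gts, breed, SAFE_PATTERN)
        elif r < 0.97:  # STR-like multi-allelic, no group fixation anywhere
            ref, alts, index = plant_str_locus("T", [4, 5], [0, 1])
            low = [index[0], index[1]]
            high = [index[4], index[5]]
            pattern = [
                (low[0], low[0]),
                (low[1], low[1]),
                (high[0], high[0]),
                (high[1], high[1]),
                (low[0], high[0]),
            ]
            for breed in self.design.breeds:
                self._assign(gts, breed, pattern)
        else:  # multi-allelic without a single repeat unit (STR rejection)
            ref, alts = "A", ("AT", "ACG")
            pattern = [(0, 0), (0, 0), (1, 1), (2, 2), (0, 1)]
            for breed in self.design.breeds:
                self._assign(gts, breed, pattern)
        ann = None
        if self.rng.random() < 0.5:
            gene = f"LOC{int(self.rng.integers(100000, 999999))}"
            term = "intron_variant" if self.rng.random() < 0.6 else "intergenic_variant"
            ann = _ann_entry(alts[0], term, gene)
        self.loci.append(
            _Locus(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=alts,
                gts=gts,
                ann=ann,
                background=True,
            )
        )

    # -- depth / AD --------------------------------------------------------

    def _depth(self, chrom: str, background: bool) -> int:
        d = self.design
        lo = d.depth_min_x if chrom == "chrX" else d.depth_min
        thresh = 5 if chrom == "chrX" else 10
        if background and self.rng.random() < d.dropout_rate:
            return int(self.rng.integers(0, thresh))
        return int(self.rng.integers(lo, d.depth_mean + 10))

    def allele_depths(self, locus: _Locus) -> list:
        n_alleles = 1 + len(locus.alts)
        out = []
        for i, gt in enumerate(locus.gts):
            if i in locus.depth_override:
                total = locus.depth_override[i]
            else:
                total = self._depth(locus.chrom, locus.background)
            ad = [0] * n_alleles
            a, b = gt
            if a == b:
                ad[a] = total
            else:
                half = total // 2
                ad[a] = total - half
                ad[b] = half
            out.append(ad)
        return out


def _plant_default_features(b: _Builder, cfg_x_par_end: int = 6_600_000):
    breeds = b.design.breed_names
    rng = b.rng

    # --- chr1: one BSGS of each type per breed -------------------------------
    for i, breed in enumerate(breeds):
        gene, term, prot = "", "", ""
        if i == 0:
            gene, term, prot = "EIPR1", "missense_variant", "44/317"
        b.add_biallelic(
            "chr1",
            100_000 + i * 37_000,
            (breed,),
            kind="BSGS_SNP",
            expect_bsgs=True,
            gene=gene,
            effect_term=term,
            protein_change=prot,
        )
    indel_alts = ["ATT", "ACTG", "AGG", "AT", "ATTC", "AGTCA", "ACC", "AGA"]
    for i, breed in enumerate(breeds):
        gene, term, prot = "", "", ""
        if i == 1:
            gene, term, prot = "ZDHHC1", "frameshift_variant", "156/511"
        if i == 2:
            gene, term, prot = "CENPU", "conservative_inframe_deletion", "84/422"
        b.add_biallelic(
            "chr1",
            800_000 + i * 31_000,
            (breed,),
            kind="BSGS_INDEL",
            alt=indel_alts[i],
            expect_bsgs=True,
            gene=gene,
            effect_term=term,
            protein_change=prot,
        )
    # a long INDEL: breed-enriched but excluded from the short-INDEL catalog
    b.add_biallelic(
        "chr1",
        1_200_000,
        (breeds[2],),
        kind="LONG_INDEL_GS",
        alt="A" + "T" * 12,
        expect_gs=True,
        expect_bsgs=False,
    )
    # STR signatures: alternating expansion / contraction
    units = ["TTCT", "AC", "T", "AGAT", "CT", "TG", "A", "TTG"]
    anchors = ["A", "G", "C", "G", "C", "T", "T", "A"]
    for i, breed in enumerate(breeds):
        unit, anchor = units[i], anchors[i]
        if unit == anchor:
            anchor = "G"  # anchor must not extend the repeat ambiguously
        if i % 2 == 0:
            carrier_counts, other_counts, sig = [8, 9, 10], [0, 1, 2, 3], "EXPANSION"
        elif i == 5:
            carrier_counts, other_counts, sig = [4], [0, 1, 2], "EXPANSION"
        else:
            carrier_counts, other_counts, sig = [0], [3, 4], "CONTRACTION"
        b.add_str(
            "chr1",
            1_500_000 + i * 29_000,
            breed,
            unit=unit,
            anchor=anchor,
            carrier_counts=carrier_counts,
            other_counts=other_counts,
            signature_type=sig,
        )

    # --- chr1 decoys: each fails exactly one rule ----------------------------
    b.add_biallelic(
        "chr1",
        2_000_000,
        (breeds[0],),
        kind="NEAR_MISS_DECOY",
        expect_gs=False,
        expect_bsgs=False,
        decoy_rule="frequency",
        carrier_override_code="ONE_HET",
    )
    sl = b.breed_slices[breeds[1]]
    b.add_biallelic(
        "chr1",
        2_050_000,
        (breeds[1],),
        kind="NEAR_MISS_DECOY",
        expect_gs=False,
        expect_bsgs=False,
        decoy_rule="validity",
        depth_override={i: 3 for i in range(sl.start, sl.start + 3)},
    )
    low_depth = {}
    for other in breeds[3:]:
        sl = b.breed_slices[other]
        low_depth.update({i: 2 for i in range(sl.start, sl.start + 3)})
    b.add_biallelic(
        "chr1",
        2_100_000,
        (breeds[2],),
        kind="NEAR_MISS_DECOY",
        expect_gs=False,
        expect_bsgs=False,
        decoy_rule="reference_support",
        depth_override=low_depth,
    )
    b.add_biallelic(
        "chr1",
        2_150_000,
        tuple(breeds[:3]),
        kind="GS",
        expect_gs=True,
        expect_pair=False,
        decoy_rule="pair_excess",
    )
    b.add_str(
        "chr1",
        2_200_000,
        breeds[3],
        unit="GT",
        anchor="C",
        carrier_counts=[6, 7],
        other_counts=[0, 1],
        signature_type="EXPANSION",
        expect_bsgs=False,
        kind="NEAR_MISS_DECOY",
        decoy_rule="frequency",
        carrier_mixed_dog=True,
    )

    # --- chr1 positional clusters -------------------------------------------
    stretch_offsets = [0, 95, 190, 300, 400, 510, 620, 700, 800, 900, 1000, 1080, 1166]
    for off in stretch_offsets:
        b.add_biallelic(
            "chr1",
            2_600_000 + off,
            (breeds[0],),
            kind="BSGS_SNP",
            expect_bsgs=True,
            gene="NOTO-RAB11FIP5",
            effect_term="intergenic_variant",
            cluster="stretch1",
        )
    for j in range(6):
        b.add_biallelic(
            "chr1",
            3_000_000 + j * 8_000,
            (breeds[2],),
            kind="BSGS_SNP",
            expect_bsgs=True,
            gene="ZNF423",
            effect_term="intron_variant",
            cluster="hotspot1",
        )

    # --- chr2: multi-type structure for one breed ----------------------------
    struct_breed = breeds[3]
    struct_pos = [
        1_000_000, 1_015_000, 1_030_000, 1_045_000, 1_060_000, 1_075_000,
        1_090_000, 1_105_000, 1_125_000, 1_145_000, 1_162_000, 1_180_000,
    ]
    for k, pos in enumerate(struct_pos):
        if k == 2:
            b.add_biallelic(
                "chr2", pos, (struct_breed,), kind="BSGS_INDEL", alt="ATTA",
                expect_bsgs=True, gene=f"LOC55{k:04d}",
                effect_term="intron_variant", cluster="structure1",
            )
        elif k == 6:
            b.add_str(
                "chr2", pos, struct_breed, unit="TG", anchor="C",
                carrier_counts=[7, 8], other_counts=[0, 1, 2],
                signature_type="EXPANSION", cluster="structure1",
            )
        else:
            gene = "OTOGL" if k == 0 else f"LOC56{k:04d}"
            term = "missense_variant" if k == 0 else "intron_variant"
            prot = "1194/2343" if k == 0 else ""
            b.add_biallelic(
                "chr2", pos, (struct_breed,), kind="BSGS_SNP",
                expect_bsgs=True, gene=gene, effect_term=term,
                protein_change=prot, cluster="structure1",
            )

    # --- chr2: breed-pair-exclusive signatures -------------------------------
    pair_plan = [
        (breeds[0], breeds[2]), (breeds[0], breeds[2]), (breeds[0], breeds[2]),
        (breeds[4], breeds[7]), (breeds[4], breeds[7]),
        (breeds[5], breeds[6]),
        (breeds[1], breeds[3]),
    ]
    for j, pair in enumerate(pair_plan):
        b.add_biallelic(
            "chr2",
            2_000_000 + j * 40_000,
            pair,
            kind="PAIR_SIGNATURE",
            expect_gs=True,
            expect_pair=True,
        )

    # --- chr2: multi-carrier GS ----------------------------------------------
    for j in range(10):
        size = int(rng.integers(3, 5))
        carriers = tuple(
            sorted(rng.choice(breeds, size=size, replace=False).tolist())
        )
        b.add_biallelic(
            "chr2", 3_000_000 + j * 35_000, carriers, kind="GS", expect_gs=True
        )

    # --- chr2: reference-orientation signatures and universal loci -----------
    for j, breed in enumerate(breeds[3:5]):
        b.add_biallelic(
            "chr2",
            4_000_000 + j * 50_000,
            (breed,),
            kind="BSGS_SNP",
            orientation="REFERENCE",
            expect_bsgs=True,
        )
    b.add_biallelic(
        "chr2",
        4_100_000,
        tuple(breeds[5:8]),
        kind="GS",
        orientation="REFERENCE",
        expect_gs=True,
    )
    for j in range(3):
        b.add_biallelic(
            "chr2",
            4_200_000 + j * 10_000,
            tuple(breeds),
            kind="UNIVERSAL",
            expect_gs=False,
            expect_bsgs=False,
        )

    # --- chrX: PAR enrichment and X-specific BSGS ----------------------------
    def par_gs(pos):
        size = int(rng.integers(3, 5))
        carriers = tuple(
            sorted(rng.choice(breeds, size=size, replace=False).tolist())
        )
        b.add_biallelic(
            "chrX", pos, carriers, kind="GS", expect_gs=True, cluster="par"
        )

    for j in range(45):
        par_gs(500_001 + j * 220)  # one dense block (index 50)
    for j in range(50):
        par_gs(1_200_001 + j * 190)  # one dense block (index 120)
    for j in range(12):
        par_gs(3_000_001 + j * 800)  # a moderate block (index 300)
    for j in range(20):
        par_gs(4_000_000 + j * 25_000)  # scattered PAR background signatures
    for j in range(15):
        size = int(rng.integers(3, 5))
        carriers = tuple(
            sorted(rng.choice(breeds, size=size, replace=False).tolist())
        )
        b.add_biallelic(
            "chrX", 6_700_000 + j * 50_000, carriers, kind="GS", expect_gs=True
        )
    for j, breed in enumerate(breeds[:5]):
        b.add_biallelic(
            "chrX",
            7_500_000 + j * 20_000,
            (breed,),
            kind="BSGS_SNP",
            expect_bsgs=True,
        )


def simulate_cohort(
    design: CohortDesign, seed: int, out_dir
) -> tuple[Path, Path, pd.DataFrame]:
    """Generate (VCF, panel, truth table) for a planted-truth cohort.

    Deterministic for a fixed seed: two runs produce byte-identical files.
    Returns the VCF path, the panel path and the truth table (also written
    as ``truth.tsv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    builder = _Builder(design, rng)
    _plant_default_features(builder)

    # background loci on a 10k+3 position grid (disjoint from planted sites)
    for chrom, n in design.n_background.items():
        length = design.chrom_lengths[chrom]
        grid = np.arange(1_000, (length - 1_000) // 10, dtype=np.int64)
        picks = np.sort(rng.choice(grid, size=n, replace=False)) * 10 + 3
        for pos in picks:
            builder.add_background(chrom, int(pos))

    seen = set()
    for locus in builder.loci:
        key = (locus.chrom, locus.pos)
        if key in seen:
            raise ValueError(f"duplicate planted position {key}")
        seen.add(key)
    builder.loci.sort(
        key=lambda l: (list(design.chrom_lengths).index(l.chrom), l.pos)
    )

    panel_path = out_dir / "panel.tsv"
    with open(panel_path, "w") as fh:
        for breed, n in design.breeds.items():
            for i in range(n):
                fh.write(f"{breed}_{i + 1}\t{breed}\n")

    vcf_path = out_dir / "cohort.vcf"
    samples = design.samples
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsig-simulate\n")
        for chrom, length in design.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,'
            'Description="Functional annotations">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for locus in builder.loci:
            ads = builder.allele_depths(locus)
            info = f"ANN={locus.ann}" if locus.ann else "."
            cols = [
                locus.chrom,
                str(locus.pos),
                ".",
                locus.ref,
                ",".join(locus.alts),
                ".",
                "PASS",
                info,
                "GT:AD",
            ]
            for gt, ad in zip(locus.gts, ads):
                cols.append(f"{gt[0]}/{gt[1]}:" + ",".join(map(str, ad)))
            fh.write("\t".join(cols) + "\n")

    truth_rows = [l.truth for l in builder.loci if l.truth is not None]
    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return vcf_path, panel_path, truth
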