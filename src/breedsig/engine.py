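"""Population-frequency analysis: BVF computation and signature scans.

The breed variant frequency (BVF) of a breed at a locus is the fraction of
its solid-call dogs that are homozygous for an oriented allele state.  Four
orientations exist: the alternative allele, the reference allele, and — for
accepted STR loci — the high- and low-repeat group.  A genetic signature
(GS) is a locus+orientation carried (BVF >= bvf_high) by at least one valid
breed; a breed-specific genetic signature (BSGS) additionally requires
exactly one carrier breed with every other valid breed at BVF <= bvf_low.
Both orientations are scanned at every locus and the results unioned;
oriented states carried homozygously by every solid dog in the cohort
("universal" states, attributable to the reference individual) are excluded.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .config import ThresholdConfig
from .io import (
    BreedPanel,
    EffectAnnotation,
    VariantClass,
    VariantLocus,
    classify_variant,
    chrom_sort_key,
    stream_variants,
)
from .qc import (
    SolidCallMask,
    locus_valid_breeds,
    reference_solid_count,
    solid_call_mask,
)
from .str_typing import (
    STRGroupCall,
    STRLocusModel,
    decompose_str_locus,
    sample_group_call,
)

__all__ = [
    "Orientation",
    "VariantType",
    "BreedStat",
    "BVFRecord",
    "SignatureRecord",
    "BSGSRecord",
    "STRSignatureType",
    "compute_bvf",
    "is_universal_variant",
    "scan_gs",
    "scan_bsgs",
    "scan_pair_signatures",
    "scan_str_signatures",
    "scan_locus",
    "scan_cohort",
    "Catalogs",
]


class Orientation(Enum):
    VARIANT = "VARIANT"
    REFERENCE = "REFERENCE"
    STR_HIGH = "STR_HIGH"
    STR_LOW = "STR_LOW"


class VariantType(Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    STR = "STR"


class STRSignatureType(Enum):
    EXPANSION = "EXPANSION"
    CONTRACTION = "CONTRACTION"


@dataclass(frozen=True)
class BreedStat:
    n_carriers: int
    n_solid: int

    @property
    def bvf(self) -> float:
        return self.n_carriers / self.n_solid


@dataclass(frozen=True)
class BVFRecord:
    """Per-valid-breed homozygous-carrier frequencies for one orientation."""

    chrom: str
    pos: int
    orientation: Orientation
    per_breed: dict  # breed -> BreedStat, valid breeds only
    n_solid_total: int  # solid samples over the whole cohort
    n_carrier_total: int  # oriented-state carriers over the whole cohort

    def bvf(self, breed: str) -> float:
        return self.per_breed[breed].bvf


@dataclass(frozen=True)
class SignatureRecord:
    """A locus+orientation carried by one or more valid breeds (a GS)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: VariantType
    orientation: Orientation
    carrier_breeds: frozenset
    n_reference_solid: int
    annotations: tuple = ()

    @property
    def effect_terms(self) -> tuple:
        return tuple(a.effect_term for a in self.annotations)

    @property
    def region_label(self) -> str:
        for a in self.annotations:
            if a.region_label:
                return a.region_label
        return ""


@dataclass(frozen=True)
class BSGSRecord(SignatureRecord):
    """A GS with exactly one carrier breed (breed-specific)."""

    is_functional: bool = False
    signature_type: Optional[STRSignatureType] = None
    unit: str = ""
    carrier_repeat_range: str = ""
    reference_repeat_range: str = ""
    unit_diff: int = 0
    large_repeat_diff: bool = False

    @property
    def breed(self) -> str:
        (b,) = self.carrier_breeds
        return b


# ---------------------------------------------------------------------------
# BVF
# ---------------------------------------------------------------------------


def _carrier_flags_biallelic(
    locus: VariantLocus, orientation: Orientation
) -> np.ndarray:
    target = 1 if orientation is Orientation.VARIANT else 0
    return np.fromiter(
        (gt is not None and gt == (target, target) for gt in locus.genotypes),
        dtype=bool,
        count=locus.n_samples,
    )


def _carrier_flags_str(
    calls: Sequence[STRGroupCall], orientation: Orientation
) -> np.ndarray:
    target = (
        STRGroupCall.HIGH if orientation is Orientation.STR_HIGH else STRGroupCall.LOW
    )
    return np.fromiter((c is target for c in calls), dtype=bool, count=len(calls))


def _bvf_from_flags(
    chrom: str,
    pos: int,
    orientation: Orientation,
    carrier: np.ndarray,
    mask: SolidCallMask,
    panel: BreedPanel,
    cfg: ThresholdConfig,
) -> BVFRecord:
    carrier = carrier & mask.solid  # only solid dogs count anywhere
    per_breed = {}
    for breed in panel.breeds:
        n_solid = mask.breed_solid_n[breed]
        if n_solid < cfg.min_breed_n:
            continue
        idx = panel.breed_sample_indices(breed)
        per_breed[breed] = BreedStat(
            n_carriers=int(carrier[idx].sum()), n_solid=n_solid
        )
    return BVFRecord(
        chrom=chrom,
        pos=pos,
        orientation=orientation,
        per_breed=per_breed,
        n_solid_total=mask.n_solid,
        n_carrier_total=int(carrier.sum()),
    )


def compute_bvf(
    locus: VariantLocus,
    orientation: Orientation,
    panel: BreedPanel,
    mask: SolidCallMask,
    cfg: ThresholdConfig,
    str_calls: Optional[Sequence[STRGroupCall]] = None,
) -> BVFRecord:
    """BVF record for one locus and one allele orientation.

    VARIANT/REFERENCE orientations require a bi-allelic locus; the STR
    orientations require the per-sample group calls of an accepted STR model.
    Heterozygous (and MIXED) dogs stay in the denominator but never the
    numerator.
    """
    if orientation in (Orientation.VARIANT, Orientation.REFERENCE):
        if len(locus.alts) != 1:
            raise ValueError(
                f"{locus.chrom}:{locus.pos}: {orientation.value} orientation "
                "requires a bi-allelic locus"
            )
        carrier = _carrier_flags_biallelic(locus, orientation)
    else:
        if str_calls is None:
            raise ValueError("STR orientations require per-sample group calls")
        carrier = _carrier_flags_str(str_calls, orientation)
    return _bvf_from_flags(
        locus.chrom, locus.pos, orientation, carrier, mask, panel, cfg
    )


def is_universal_variant(bvf: BVFRecord) -> bool:
    """True iff every solid dog in the cohort carries the oriented state."""
    if bvf.n_solid_total == 0:
        warnings.warn(
            f"{bvf.chrom}:{bvf.pos}: no solid calls; universal check vacuous"
        )
        return False
    return bvf.n_carrier_total == bvf.n_solid_total


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _carriers(bvf: BVFRecord, cfg: ThresholdConfig) -> frozenset:
    return frozenset(
        b for b, st in bvf.per_breed.items() if st.bvf >= cfg.bvf_high
    )


def _others_low(bvf: BVFRecord, carriers: frozenset, cfg: ThresholdConfig) -> bool:
    return all(
        st.bvf <= cfg.bvf_low
        for b, st in bvf.per_breed.items()
        if b not in carriers
    )


def _ref_support(
    carriers: frozenset, mask: SolidCallMask, bvf: BVFRecord, cfg: ThresholdConfig
) -> Optional[int]:
    """Reference solid count if the candidate passes the filter, else None."""
    valid = frozenset(bvf.per_breed)
    n_ref = reference_solid_count(carriers, mask, valid)
    return n_ref if n_ref >= cfg.min_reference_n else None


def _base_record(
    locus: VariantLocus,
    bvf: BVFRecord,
    carriers: frozenset,
    n_ref: int,
    variant_type: VariantType,
) -> SignatureRecord:
    return SignatureRecord(
        chrom=locus.chrom,
        pos=locus.pos,
        ref=locus.ref,
        alt=",".join(locus.alts),
        variant_type=variant_type,
        orientation=bvf.orientation,
        carrier_breeds=carriers,
        n_reference_solid=n_ref,
        annotations=tuple(locus.annotations),
    )


def scan_gs(
    locus: VariantLocus,
    bvf: BVFRecord,
    mask: SolidCallMask,
    cfg: ThresholdConfig,
    variant_type: VariantType,
) -> Optional[SignatureRecord]:
    """Breed-enriched scan: any valid breed fixed at BVF >= bvf_high."""
    if is_universal_variant(bvf):
        return None
    carriers = _carriers(bvf, cfg)
    if not carriers:
        return None
    n_ref = _ref_support(carriers, mask, bvf, cfg)
    if n_ref is None:
        return None
    return _base_record(locus, bvf, carriers, n_ref, variant_type)


def scan_bsgs(
    locus: VariantLocus,
    bvf: BVFRecord,
    mask: SolidCallMask,
    cfg: ThresholdConfig,
    variant_type: VariantType,
) -> Optional[BSGSRecord]:
    """Breed-specific scan: exactly one carrier, all other valid breeds low.

    INDEL candidates additionally require an allele-length difference below
    ``max_short_indel`` (the short-INDEL reporting rule); the rule does not
    apply to the breed-enriched (GS) scan.
    """
    if is_universal_variant(bvf):
        return None
    carriers = _carriers(bvf, cfg)
    if len(carriers) != 1 or not _others_low(bvf, carriers, cfg):
        return None
    if variant_type is VariantType.INDEL:
        size = abs(len(locus.ref) - len(locus.alts[0]))
        if size >= cfg.max_short_indel:
            return None
    n_ref = _ref_support(carriers, mask, bvf, cfg)
    if n_ref is None:
        return None
    base = _base_record(locus, bvf, carriers, n_ref, variant_type)
    return BSGSRecord(
        **{k: getattr(base, k) for k in base.__dataclass_fields__},
        is_functional=cfg.is_functional(base.effect_terms),
    )


def scan_pair_signatures(
    locus: VariantLocus,
    bvf: BVFRecord,
    mask: SolidCallMask,
    cfg: ThresholdConfig,
    variant_type: VariantType,
) -> Optional[tuple[tuple[str, str], SignatureRecord]]:
    """Breed-pair-exclusive scan: exactly two carriers, all others low."""
    if is_universal_variant(bvf):
        return None
    carriers = _carriers(bvf, cfg)
    if len(carriers) != 2 or not _others_low(bvf, carriers, cfg):
        return None
    n_ref = _ref_support(carriers, mask, bvf, cfg)
    if n_ref is None:
        return None
    pair = tuple(sorted(carriers))
    return pair, _base_record(locus, bvf, carriers, n_ref, variant_type)


def scan_str_signatures(
    locus: VariantLocus,
    model: STRLocusModel,
    calls: Sequence[STRGroupCall],
    panel: BreedPanel,
    mask: SolidCallMask,
    cfg: ThresholdConfig,
) -> list[SignatureRecord]:
    """GS and BSGS scans on the STR_HIGH and STR_LOW orientations.

    A breed-specific record is labelled EXPANSION when the carrier breed is
    fixed in the high-repeat group and CONTRACTION when fixed in the low
    group; ``unit_diff`` is the repeat-count gap between the groups and
    records with ``unit_diff >= repeat_diff_report`` carry the large-repeat
    flag.
    """
    out: list[SignatureRecord] = []
    for orientation in (Orientation.STR_HIGH, Orientation.STR_LOW):
        bvf = compute_bvf(locus, orientation, panel, mask, cfg, str_calls=calls)
        gs = scan_gs(locus, bvf, mask, cfg, VariantType.STR)
        if gs is None:
            continue
        bs = scan_bsgs(locus, bvf, mask, cfg, VariantType.STR)
        if bs is not None:
            carrier_high = orientation is Orientation.STR_HIGH
            carrier_counts = model.high_group if carrier_high else model.low_group
            other_counts = model.low_group if carrier_high else model.high_group
            bs = replace(
                bs,
                signature_type=STRSignatureType.EXPANSION
                if carrier_high
                else STRSignatureType.CONTRACTION,
                unit=model.unit,
                carrier_repeat_range=model.range_notation(carrier_counts),
                reference_repeat_range=model.range_notation(other_counts),
                unit_diff=model.unit_diff,
                large_repeat_diff=model.unit_diff >= cfg.repeat_diff_report,
            )
            out.append(bs)
        out.append(gs)
    return out


@dataclass
class LocusScan:
    """Everything discovered at one locus."""

    variant_class: VariantClass
    gs: list = field(default_factory=list)
    bsgs: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    str_model: Optional[STRLocusModel] = None


def scan_locus(
    locus: VariantLocus,
    panel: BreedPanel,
    cfg: ThresholdConfig,
    scan_pairs: bool = True,
) -> LocusScan:
    """Run every applicable orientation at one locus and union the results.

    Bi-allelic SNPs and INDELs are scanned in VARIANT and REFERENCE
    orientations; multi-allelic INDEL candidates go through STR detection
    and, if accepted, are scanned in the repeat-group orientations.
    Pair-exclusive scanning is restricted to SNPs by the pipeline (the
    published pair catalog is SNP-based) but available for any bi-allelic
    type through :func:`scan_pair_signatures`.
    """
    vclass = classify_variant(locus)
    result = LocusScan(variant_class=vclass)
    if vclass is VariantClass.OTHER:
        return result
    mask = solid_call_mask(locus, panel, cfg)

    if vclass is VariantClass.MULTIALLELIC_INDEL_CANDIDATE:
        model = decompose_str_locus(
            locus.alleles, cfg, chrom=locus.chrom, pos=locus.pos
        )
        result.str_model = model
        if model is None:
            return result
        calls = [
            sample_group_call(gt, ad, model, locus.chrom, cfg)
            for gt, ad in zip(locus.genotypes, locus.allele_depths)
        ]
        for rec in scan_str_signatures(locus, model, calls, panel, mask, cfg):
            (result.bsgs if isinstance(rec, BSGSRecord) else result.gs).append(rec)
        return result

    variant_type = (
        VariantType.SNP if vclass is VariantClass.SNP else VariantType.INDEL
    )
    seen: set[tuple[Orientation, frozenset]] = set()
    for orientation in (Orientation.VARIANT, Orientation.REFERENCE):
        bvf = compute_bvf(locus, orientation, panel, mask, cfg)
        gs = scan_gs(locus, bvf, mask, cfg, variant_type)
        if gs is not None:
            key = (orientation, gs.carrier_breeds)
            assert key not in seen, "duplicate record for one orientation"
            seen.add(key)
            result.gs.append(gs)
        bs = scan_bsgs(locus, bvf, mask, cfg, variant_type)
        if bs is not None:
            result.bsgs.append(bs)
        if scan_pairs and variant_type is VariantType.SNP:
            pr = scan_pair_signatures(locus, bvf, mask, cfg, variant_type)
            if pr is not None:
                result.pairs.append(pr)
    return result


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------


@dataclass
class Catalogs:
    """Coordinate-sorted discovery catalogs for one cohort scan."""

    gs: list = field(default_factory=list)  # SignatureRecords, all types
    bsgs_snp: list = field(default_factory=list)
    bsgs_indel: list = field(default_factory=list)
    bsgs_str: list = field(default_factory=list)
    pairs: list = field(default_factory=list)  # (breed pair, SignatureRecord)
    n_loci: int = 0
    n_str_loci: int = 0

    def bsgs_all(self) -> list:
        return self.bsgs_snp + self.bsgs_indel + self.bsgs_str


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**63
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def scan_cohort(
    vcf_path,
    panel: BreedPanel,
    cfg: ThresholdConfig,
    threads: int = 1,
    region: Optional[str] = None,
    variant_classes: Optional[Iterable[str]] = None,
    effect_terms: Optional[Iterable[str]] = None,
    log=None,
) -> Catalogs:
    """Scan a whole VCF and collect every catalog.

    ``region`` (``chrom`` or ``chrom:start-end``), ``variant_classes`` and
    ``effect_terms`` implement the variant selector: they restrict the loci
    entering frequency analysis, and commute with per-record filtering of the
    unrestricted output.  Output is independent of ``threads`` — work is
    partitioned by chromosome and reassembled in input order.
    """
    want_class = (
        {VariantClass(c) for c in variant_classes} if variant_classes else None
    )
    want_terms = set(effect_terms) if effect_terms else None
    sel = _parse_region(region) if region else None

    def keep(locus: VariantLocus) -> bool:
        if sel is not None:
            chrom, start, end = sel
            if locus.chrom != chrom or not (start <= locus.pos <= end):
                return False
        if want_terms is not None and not (
            want_terms & set(locus.effect_terms())
        ):
            return False
        return True

    # group loci by chromosome, preserving file order
    by_chrom: dict[str, list[VariantLocus]] = defaultdict(list)
    for locus in stream_variants(vcf_path, panel):
        if keep(locus):
            by_chrom[locus.chrom].append(locus)

    def scan_one_chrom(loci: list[VariantLocus]) -> list[LocusScan]:
        return [scan_locus(locus, panel, cfg) for locus in loci]

    chroms = list(by_chrom)
    if threads > 1 and len(chroms) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            scans_per_chrom = list(
                pool.map(scan_one_chrom, (by_chrom[c] for c in chroms))
            )
    else:
        scans_per_chrom = [scan_one_chrom(by_chrom[c]) for c in chroms]

    cat = Catalogs()
    for chrom, scans in zip(chroms, scans_per_chrom):
        n_sig = 0
        for scan in scans:
            if want_class is not None and scan.variant_class not in want_class:
                continue
            cat.n_loci += 1
            if scan.str_model is not None:
                cat.n_str_loci += 1
            # scan.gs already covers every BSGS locus (BSGS c GS by construction)
            cat.gs.extend(scan.gs)
            for bs in scan.bsgs:
                {
                    VariantType.SNP: cat.bsgs_snp,
                    VariantType.INDEL: cat.bsgs_indel,
                    VariantType.STR: cat.bsgs_str,
                }[bs.variant_type].append(bs)
            cat.pairs.extend(scan.pairs)
            n_sig += len(scan.gs) + len(scan.bsgs)
        if log is not None:
            log(f"{chrom}: scanned {len(scans)} loci, {n_sig} signature records")

    key = lambda r: (chrom_sort_key(r.chrom), r.pos, r.orientation.value)
    cat.gs.sort(key=key)
    for lst in (cat.bsgs_snp, cat.bsgs_indel, cat.bsgs_str):
        lst.sort(key=key)
    cat.pairs.sort(key=lambda pr: (chrom_sort_key(pr[1].chrom), pr[1].pos))
    return cat
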