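"""Positional aggregation of signatures into segments, blocks and summaries.

Span arithmetic follows the reporting convention of the discovery engine:
a segment's length is ``(last - first)`` bp (no +1) divided by 1000, and its
density is the member count over that length; both print at two decimals.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import ThresholdConfig
from .engine import BSGSRecord, SignatureRecord, VariantType
from .io import chrom_sort_key

__all__ = [
    "MergedBSGS",
    "MergedBSGSCatalog",
    "SegmentRecord",
    "BlockSummary",
    "merge_bsgs_catalogs",
    "find_gene_hotspots",
    "find_density_stretches",
    "find_breed_structures",
    "summarize_blocks",
    "blocks_with_at_least",
    "par_summary",
]


@dataclass(frozen=True)
class MergedBSGS:
    """One (possibly multi-type) BSGS entry of the merged per-breed catalog."""

    chrom: str
    pos: int
    breed: str
    types: tuple  # VariantType members, distinct, sorted by name
    records: tuple  # underlying BSGSRecords

    @property
    def region_label(self) -> str:
        for r in self.records:
            if r.region_label:
                return r.region_label
        return ""

    @property
    def is_functional(self) -> bool:
        return any(r.is_functional for r in self.records)

    @property
    def functional_genes(self) -> tuple:
        genes = []
        for r in self.records:
            if r.is_functional:
                for a in r.annotations:
                    if a.effect_term in r.effect_terms and a.gene_label:
                        genes.append(a.gene_label)
        return tuple(dict.fromkeys(genes))

    @property
    def effect_terms(self) -> tuple:
        out = []
        for r in self.records:
            out.extend(r.effect_terms)
        return tuple(dict.fromkeys(out))


@dataclass
class MergedBSGSCatalog:
    """Coordinate-sorted merged BSGS entries, grouped per breed."""

    entries: list  # MergedBSGS, globally sorted by (chrom, pos)

    def __post_init__(self):
        self.by_breed: dict[str, list[MergedBSGS]] = {}
        for e in self.entries:
            self.by_breed.setdefault(e.breed, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_records(self) -> int:
        return sum(len(e.records) for e in self.entries)


@dataclass(frozen=True)
class SegmentRecord:
    """A breed's run of signatures: hotspot, stretch or structure."""

    breed: str
    chrom: str
    start: int
    end: int
    n_snp: int
    n_indel: int
    n_str: int
    region_label: str = ""
    functional_genes: tuple = ()
    effect_terms: tuple = ()

    @property
    def n_total(self) -> int:
        return self.n_snp + self.n_indel + self.n_str

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0

    @property
    def density(self) -> float:
        """Members per kb; infinite for zero-length (single-position) runs."""
        span_kb = self.length_kb
        return self.n_total / span_kb if span_kb > 0 else float("inf")

    @property
    def is_functional(self) -> bool:
        return bool(self.functional_genes)


def _check_sorted(records: Sequence, name: str) -> None:
    keys = [(chrom_sort_key(r.chrom), r.pos) for r in records]
    if any(b < a for a, b in zip(keys, keys[1:])):
        raise ValueError(f"{name} catalog is not coordinate-sorted")


def merge_bsgs_catalogs(
    snp: Sequence[BSGSRecord],
    indel: Sequence[BSGSRecord],
    strs: Sequence[BSGSRecord],
) -> MergedBSGSCatalog:
    """K-way merge of the three sorted per-type BSGS catalogs.

    Entries of the same breed at the same coordinate are fused into a single
    multi-type entry; record counts are conserved.
    """
    for records, name in ((snp, "SNP"), (indel, "INDEL"), (strs, "STR")):
        _check_sorted(records, name)
    merged = list(
        heapq.merge(
            snp, indel, strs, key=lambda r: (chrom_sort_key(r.chrom), r.pos)
        )
    )
    entries: list[MergedBSGS] = []
    i = 0
    while i < len(merged):
        j = i + 1
        group = [merged[i]]
        while (
            j < len(merged)
            and merged[j].chrom == merged[i].chrom
            and merged[j].pos == merged[i].pos
            and merged[j].breed == merged[i].breed
        ):
            group.append(merged[j])
            j += 1
        types = tuple(
            sorted({r.variant_type for r in group}, key=lambda t: t.name)
        )
        entries.append(
            MergedBSGS(
                chrom=merged[i].chrom,
                pos=merged[i].pos,
                breed=merged[i].breed,
                types=types,
                records=tuple(group),
            )
        )
        i = j
    return MergedBSGSCatalog(entries=entries)


def _segment_from_entries(
    entries: Sequence[MergedBSGS], region_label: str = ""
) -> SegmentRecord:
    counts = {t: 0 for t in VariantType}
    genes: list[str] = []
    terms: list[str] = []
    for e in entries:
        for r in e.records:
            counts[r.variant_type] += 1
        genes.extend(e.functional_genes)
        terms.extend(
            t for r in e.records if r.is_functional for t in r.effect_terms
        )
    return SegmentRecord(
        breed=entries[0].breed,
        chrom=entries[0].chrom,
        start=min(e.pos for e in entries),
        end=max(e.pos for e in entries),
        n_snp=counts[VariantType.SNP],
        n_indel=counts[VariantType.INDEL],
        n_str=counts[VariantType.STR],
        region_label=region_label,
        functional_genes=tuple(dict.fromkeys(genes)),
        effect_terms=tuple(dict.fromkeys(terms)),
    )


def find_gene_hotspots(
    catalog: MergedBSGSCatalog, cfg: ThresholdConfig
) -> list[SegmentRecord]:
    """Gene-labelled regions holding >= hotspot_min BSGS of one breed."""
    out: list[SegmentRecord] = []
    for breed in sorted(catalog.by_breed):
        groups: dict[tuple[str, str], list[MergedBSGS]] = {}
        for e in catalog.by_breed[breed]:
            label = e.region_label
            if not label:
                warnings.warn(
                    f"{e.chrom}:{e.pos} ({breed}): BSGS without region label; "
                    "grouped under 'unannotated'"
                )
                label = "unannotated"
            groups.setdefault((e.chrom, label), []).append(e)
        for (chrom, label), entries in groups.items():
            if sum(len(e.records) for e in entries) >= cfg.hotspot_min:
                out.append(_segment_from_entries(entries, region_label=label))
    out.sort(key=lambda s: (s.breed, chrom_sort_key(s.chrom), s.start))
    return out


def _window_qualifies(
    positions: Sequence[int], i: int, j: int, cfg: ThresholdConfig
) -> bool:
    n = j - i + 1
    if n < cfg.stretch_min:
        return False
    span = positions[j] - positions[i]
    if span == 0:
        return True
    return n / (span / 1000.0) >= cfg.stretch_density


def find_density_stretches(
    positions: Sequence[int],
    cfg: ThresholdConfig,
    breed: str = "",
    chrom: str = "",
) -> list[SegmentRecord]:
    """Maximal high-density runs in one breed's sorted positions.

    A window of consecutive members qualifies when it holds at least
    ``stretch_min`` members at >= ``stretch_density`` members/kb.  A
    qualifying window is *maximal* when extending it by one member on either
    side no longer qualifies; overlapping maximal windows are coalesced by
    keeping the longest (ties: more members, then leftmost).
    """
    pos = list(positions)
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be sorted")
    n = len(pos)
    qualifying: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + cfg.stretch_min - 1, n):
            if _window_qualifies(pos, i, j, cfg):
                qualifying.add((i, j))
    maximal = [
        (i, j)
        for (i, j) in qualifying
        if (i - 1, j) not in qualifying and (i, j + 1) not in qualifying
    ]
    maximal.sort()
    # coalesce overlapping maximal windows, keeping the longest qualifying one
    chosen: list[tuple[int, int]] = []
    cluster: list[tuple[int, int]] = []

    def flush():
        if not cluster:
            return
        best = max(
            cluster, key=lambda w: (pos[w[1]] - pos[w[0]], w[1] - w[0], -w[0])
        )
        chosen.append(best)

    for w in maximal:
        if cluster and w[0] <= cluster[-1][1]:
            cluster.append(w)
        else:
            flush()
            cluster = [w]
    flush()

    out = []
    for i, j in chosen:
        count = j - i + 1
        out.append(
            SegmentRecord(
                breed=breed,
                chrom=chrom,
                start=pos[i],
                end=pos[j],
                n_snp=count,
                n_indel=0,
                n_str=0,
            )
        )
    return out


def stretches_for_catalog(
    catalog: MergedBSGSCatalog, cfg: ThresholdConfig
) -> list[SegmentRecord]:
    """Density stretches over every breed and chromosome of a catalog."""
    out: list[SegmentRecord] = []
    for breed in sorted(catalog.by_breed):
        by_chrom: dict[str, list[int]] = {}
        for e in catalog.by_breed[breed]:
            by_chrom.setdefault(e.chrom, []).append(e.pos)
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            out.extend(
                find_density_stretches(
                    by_chrom[chrom], cfg, breed=breed, chrom=chrom
                )
            )
    return out


def find_breed_structures(
    catalog: MergedBSGSCatalog, cfg: ThresholdConfig
) -> list[SegmentRecord]:
    """Breed-specific genomic structures: gap-limited runs of >= structure_min.

    Per breed and chromosome the merged BSGS list is split wherever two
    consecutive members lie more than ``structure_gap`` bp apart (the gap
    rule is inclusive: exactly ``structure_gap`` stays joined); surviving
    runs with at least ``structure_min`` members are reported with per-type
    counts, density and functional flags.
    """
    out: list[SegmentRecord] = []
    for breed in sorted(catalog.by_breed):
        by_chrom: dict[str, list[MergedBSGS]] = {}
        for e in catalog.by_breed[breed]:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            entries = by_chrom[chrom]
            run: list[MergedBSGS] = []
            for e in entries:
                if run and e.pos - run[-1].pos > cfg.structure_gap:
                    if sum(len(x.records) for x in run) >= cfg.structure_min:
                        out.append(_segment_from_entries(run))
                    run = []
                run.append(e)
            if run and sum(len(x.records) for x in run) >= cfg.structure_min:
                out.append(_segment_from_entries(run))
    return out


@dataclass(frozen=True)
class BlockSummary:
    """GS content of one block of the genome tiling.

    Block k covers the 1-based closed interval
    ``[k*block_size + 1, (k+1)*block_size]``.
    """

    chrom: str
    block: int
    n_gs: int
    mean_breeds_per_gs: float

    def start(self, cfg: ThresholdConfig) -> int:
        return self.block * cfg.block_size + 1

    def end(self, cfg: ThresholdConfig) -> int:
        return (self.block + 1) * cfg.block_size


def summarize_blocks(
    gs: Iterable[SignatureRecord], cfg: ThresholdConfig
) -> list[BlockSummary]:
    """Tile signatures into blocks; empty blocks are omitted from the output."""
    acc: dict[tuple[str, int], list[int]] = {}
    for r in gs:
        k = (r.pos - 1) // cfg.block_size
        acc.setdefault((r.chrom, k), []).append(len(r.carrier_breeds))
    out = [
        BlockSummary(
            chrom=chrom,
            block=k,
            n_gs=len(sizes),
            mean_breeds_per_gs=float(np.mean(sizes)),
        )
        for (chrom, k), sizes in acc.items()
    ]
    out.sort(key=lambda b: (chrom_sort_key(b.chrom), b.block))
    return out


def blocks_with_at_least(
    blocks: Iterable[BlockSummary], threshold: int
) -> list[BlockSummary]:
    """Blocks holding at least ``threshold`` signatures (>=, inclusive)."""
    return [b for b in blocks if b.n_gs >= threshold]


def par_summary(
    blocks: Sequence[BlockSummary],
    gs: Sequence[SignatureRecord],
    cfg: ThresholdConfig,
) -> dict:
    """Signature summary of the X-chromosome pseudoautosomal region.

    Restricts to blocks fully inside the PAR interval and reports the GS
    count, the count (and fraction) of GS inside blocks with more than
    ``block_high`` signatures, the mean carrier-breed count per GS and the
    set of breeds represented.
    """
    x_blocks = [
        b
        for b in blocks
        if b.chrom in cfg.x_chrom_names
        and b.start(cfg) >= cfg.par_start + 1
        and b.end(cfg) <= cfg.par_end
    ]
    if not any(b.chrom in cfg.x_chrom_names for b in blocks):
        warnings.warn("no X-chromosome blocks present; PAR summary is empty")
    high = {(b.chrom, b.block) for b in x_blocks if b.n_gs > cfg.block_high}
    par_gs = [
        r
        for r in gs
        if r.chrom in cfg.x_chrom_names
        and cfg.par_start + 1 <= r.pos
        and (r.pos - 1) // cfg.block_size * cfg.block_size + cfg.block_size
        <= cfg.par_end
    ]
    n_total = len(par_gs)
    n_high = sum(
        1 for r in par_gs if (r.chrom, (r.pos - 1) // cfg.block_size) in high
    )
    breeds: set[str] = set()
    for r in par_gs:
        breeds |= set(r.carrier_breeds)
    return {
        "n_gs": n_total,
        "n_blocks": len(x_blocks),
        "n_high_blocks": len(high),
        "n_gs_in_high_blocks": n_high,
        "fraction_in_high_blocks": (n_high / n_total) if n_total else 0.0,
        "mean_breeds_per_gs": float(
            np.mean([len(r.carrier_breeds) for r in par_gs])
        )
        if par_gs
        else 0.0,
        "breeds_represented": sorted(breeds),
    }
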