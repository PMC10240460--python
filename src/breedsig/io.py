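"""Input/output: breed panels, multi-sample VCFs and TSV reports.

The VCF is consumed exactly as produced upstream (joint calling plus
SnpEff-style ANN annotation); no normalisation or re-annotation happens here.
Coordinates are 1-based inclusive throughout, following VCF convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "EffectAnnotation",
    "VariantLocus",
    "BreedPanel",
    "VariantClass",
    "read_breed_panel",
    "stream_variants",
    "classify_variant",
    "write_report",
    "parse_ann_field",
    "chrom_sort_key",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectAnnotation:
    """One parsed SnpEff ANN entry (only the subfields downstream logic uses).

    ``region_label`` is the gene symbol, or ``"geneA-geneB"`` for intergenic
    records; ``protein_change`` is ``(first impacted AA position, protein
    length)`` when the annotator printed one.
    """

    allele: str
    effect_term: str
    gene_label: str = ""
    region_label: str = ""
    protein_change: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if not self.effect_term:
            raise ValueError("effect_term must be a non-empty token")
        if self.protein_change is not None:
            pos, length = self.protein_change
            if pos > length:
                raise ValueError(
                    f"protein position {pos} exceeds protein length {length}"
                )


# sentinel: genotype present but per-allele depths unknown at this site
DEPTH_UNKNOWN = None


@dataclass
class VariantLocus:
    """One VCF site restricted to the panel's samples (panel order).

    ``genotypes[i]`` is an ``(a, b)`` pair of allele indices or ``None`` for
    a missing call; ``allele_depths[i]`` is a tuple of per-allele read counts
    (length ``1 + len(alts)``) or ``None`` when depth is unknown.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: list[Optional[tuple[int, int]]]
    allele_depths: list[Optional[tuple[int, ...]]]
    annotations: list[EffectAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError("at least one alternative allele required")
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            if gt is not None and max(gt) >= n_alleles:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: genotype allele index {max(gt)} "
                    f"out of range for {n_alleles} alleles"
                )
        for ad in self.allele_depths:
            if ad is not None and len(ad) != n_alleles:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: AD length {len(ad)} != {n_alleles}"
                )

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def effect_terms(self) -> list[str]:
        return [a.effect_term for a in self.annotations]


@dataclass
class BreedPanel:
    """Sample -> breed assignment plus the derived breed -> samples map."""

    assignments: dict[str, str]

    def __post_init__(self):
        for sample, breed in self.assignments.items():
            if not breed:
                raise ValueError(f"empty breed name for sample {sample!r}")
        self.breeds: dict[str, list[str]] = {}
        for sample, breed in self.assignments.items():
            self.breeds.setdefault(breed, []).append(sample)
        self.samples: list[str] = list(self.assignments)
        # per-sample breed labels aligned to sample order
        self.sample_breeds: list[str] = [self.assignments[s] for s in self.samples]
        self._breed_indices: dict[str, np.ndarray] = {
            breed: np.array(
                [i for i, b in enumerate(self.sample_breeds) if b == breed],
                dtype=int,
            )
            for breed in self.breeds
        }

    @property
    def breed_names(self) -> list[str]:
        return sorted(self.breeds)

    def breed_sample_indices(self, breed: str) -> np.ndarray:
        return self._breed_indices[breed]

    def __len__(self) -> int:
        return len(self.assignments)


class VariantClass(Enum):
    """Mutually exclusive, exhaustive classification of a VCF site."""

    SNP = "SNP"
    BIALLELIC_INDEL = "BIALLELIC_INDEL"
    MULTIALLELIC_INDEL_CANDIDATE = "MULTIALLELIC_INDEL_CANDIDATE"
    OTHER = "OTHER"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_breed_panel(path) -> BreedPanel:
    """Parse a two-column (sample TAB breed) panel file.

    Blank lines and ``#`` comments are ignored.  Duplicate sample ids are a
    validation error; an empty panel is allowed with a warning.
    """
    assignments: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(
                f"{path}:{lineno}: expected 'sample<TAB>breed', got {raw!r}"
            )
        sample, breed = parts
        if sample in assignments:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        assignments[sample] = breed
    if not assignments:
        warnings.warn(f"breed panel {path} is empty")
    return BreedPanel(assignments)


_ANN_PROT_RE = re.compile(r"^(\d+)/(\d+)")


def parse_ann_field(ann: str) -> list[EffectAnnotation]:
    """Parse a SnpEff-style pipe-delimited ANN INFO value.

    Only the allele, effect term, gene symbol and protein-position subfields
    are retained; everything else is ignored.  Multiple effect terms joined
    with ``&`` are split into separate annotations.
    """
    out: list[EffectAnnotation] = []
    for entry in ann.split(","):
        sub = entry.split("|")
        if len(sub) < 2 or not sub[1]:
            continue
        allele = sub[0]
        gene = sub[3] if len(sub) > 3 else ""
        prot = None
        if len(sub) > 13 and sub[13]:
            m = _ANN_PROT_RE.match(sub[13])
            if m:
                prot = (int(m.group(1)), int(m.group(2)))
        for term in sub[1].split("&"):
            if term:
                out.append(
                    EffectAnnotation(
                        allele=allele,
                        effect_term=term,
                        gene_label=gene,
                        region_label=gene,
                        protein_change=prot,
                    )
                )
    return out


def stream_variants(path, panel: BreedPanel) -> Iterator[VariantLocus]:
    """Yield :class:`VariantLocus` records from a VCF in file order.

    Samples are restricted and reordered to the panel's order.  Sites lacking
    a usable AD FORMAT field are yielded with every sample depth-unknown (they
    will subsequently fail the solid-call filter).
    """
    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s for s in panel.samples if s not in vcf_samples]
    if missing:
        raise ValueError(
            f"panel samples absent from VCF header: {', '.join(sorted(missing))}"
        )
    order = [vcf_samples.index(s) for s in panel.samples]

    for v in vcf:
        alts = tuple(v.ALT)
        if not alts:
            continue
        n_alleles = 1 + len(alts)
        gts: list[Optional[tuple[int, int]]] = []
        for i in order:
            g = v.genotypes[i]
            a, b = int(g[0]), int(g[1]) if len(g) > 2 else int(g[0])
            if a < 0 or b < 0:
                gts.append(None)
            else:
                gts.append((a, b))
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        depths: list[Optional[tuple[int, ...]]]
        if ad is None:
            depths = [DEPTH_UNKNOWN] * len(order)
        else:
            depths = []
            for i in order:
                row = ad[i]
                if len(row) != n_alleles or any(int(x) < 0 for x in row):
                    depths.append(DEPTH_UNKNOWN)
                else:
                    depths.append(tuple(int(x) for x in row))
        ann = v.INFO.get("ANN")
        annotations = parse_ann_field(ann) if ann else []
        yield VariantLocus(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=alts,
            genotypes=gts,
            allele_depths=depths,
            annotations=annotations,
        )


def classify_variant(locus: VariantLocus) -> VariantClass:
    """Assign a locus to the analysis class its alleles imply.

    SNP: one alt, both alleles single-base.  Bi-allelic INDEL: one alt,
    lengths differ.  Multi-allelic INDEL candidate (the STR detection pool):
    >= 2 alts with at least two alleles of different length.  Everything else
    (multi-allelic SNPs, MNPs) is OTHER and excluded from all scans.
    """
    if len(locus.alts) == 1:
        alt = locus.alts[0]
        if len(locus.ref) == 1 and len(alt) == 1:
            return VariantClass.SNP
        if len(locus.ref) != len(alt):
            return VariantClass.BIALLELIC_INDEL
        return VariantClass.OTHER
    lengths = {len(a) for a in locus.alleles}
    if len(lengths) >= 2:
        return VariantClass.MULTIALLELIC_INDEL_CANDIDATE
    return VariantClass.OTHER


_NUM_RE = re.compile(r"^(?:chr)?(\d+)$")


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chrX < other."""
    m = _NUM_RE.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


_ROUND_COLS = ("length_kb", "density", "bvf", "score", "fraction", "mean_breeds")


def write_report(records, path, columns: Sequence[str]) -> None:
    """Write homogeneous records as a deterministic TSV report.

    Records may be dicts or objects with attributes matching ``columns``.
    Numeric density/length-style columns are rounded to two decimals; rows
    are sorted by (chrom, pos, breed) where those columns exist, so identical
    record sets always produce byte-identical files.
    """
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append({c: rec.get(c) for c in columns})
        else:
            rows.append({c: getattr(rec, c) for c in columns})
    df = pd.DataFrame(rows, columns=list(columns))
    sort_cols = [c for c in ("chrom", "pos", "breed") if c in df.columns]
    if sort_cols and len(df):
        if "chrom" in sort_cols:
            df["_ck"] = df["chrom"].map(chrom_sort_key)
            df = df.sort_values(
                ["_ck" if c == "chrom" else c for c in sort_cols], kind="mergesort"
            ).drop(columns="_ck")
        else:
            df = df.sort_values(sort_cols, kind="mergesort")
    for col in df.columns:
        if col in _ROUND_COLS and len(df):
            df[col] = df[col].map(
                lambda x: "" if x is None or (isinstance(x, float) and np.isnan(x))
                else f"{x:.2f}"
            )
    df.to_csv(path, sep="\t", index=False)
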