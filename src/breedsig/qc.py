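"""Per-locus, per-sample genotype quality control.

The quality filter operates at a per-locus granularity: a sample's call is
*solid* when its genotype is non-missing and the summed read depth of the
allele types it carries meets the chromosome-class threshold (10 reads on
autosomes, 5 on X).  A breed is *valid* at a locus when at least
``min_breed_n`` of its dogs have solid calls there; validity is recomputed
independently at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .config import ThresholdConfig
from .io import BreedPanel, VariantLocus

__all__ = [
    "effective_depth",
    "is_solid_call",
    "SolidCallMask",
    "solid_call_mask",
    "locus_valid_breeds",
    "passes_reference_support",
]


def effective_depth(
    genotype: Optional[tuple[int, int]],
    depths: Optional[tuple[int, ...]],
) -> Optional[int]:
    """Summed depth over the *distinct* allele types in the genotype.

    A homozygous 1/1 call contributes only AD[1]; a heterozygous 0/1 call
    contributes AD[0] + AD[1].  Returns None when the genotype is missing or
    the depths are unknown.
    """
    if genotype is None or depths is None:
        return None
    return sum(depths[a] for a in set(genotype))


def is_solid_call(
    genotype: Optional[tuple[int, int]],
    depths: Optional[tuple[int, ...]],
    chrom: str,
    cfg: ThresholdConfig,
) -> bool:
    """True iff the genotype is callable at this site's depth threshold."""
    d = effective_depth(genotype, depths)
    return d is not None and d >= cfg.depth_threshold(chrom)


@dataclass
class SolidCallMask:
    """Per-sample solid flags at one locus plus derived per-breed counts."""

    solid: np.ndarray  # bool, aligned to panel sample order
    breed_solid_n: dict[str, int]

    @property
    def n_solid(self) -> int:
        return int(self.solid.sum())


def solid_call_mask(
    locus: VariantLocus, panel: BreedPanel, cfg: ThresholdConfig
) -> SolidCallMask:
    solid = np.fromiter(
        (
            is_solid_call(gt, ad, locus.chrom, cfg)
            for gt, ad in zip(locus.genotypes, locus.allele_depths)
        ),
        dtype=bool,
        count=locus.n_samples,
    )
    counts = {
        breed: int(solid[panel.breed_sample_indices(breed)].sum())
        for breed in panel.breeds
    }
    return SolidCallMask(solid=solid, breed_solid_n=counts)


def locus_valid_breeds(
    mask: SolidCallMask, cfg: ThresholdConfig
) -> frozenset[str]:
    """Breeds with at least ``min_breed_n`` solid dogs at this locus."""
    return frozenset(
        b for b, n in mask.breed_solid_n.items() if n >= cfg.min_breed_n
    )


def passes_reference_support(
    carrier_breeds: Iterable[str],
    mask: SolidCallMask,
    cfg: ThresholdConfig,
    valid_breeds: Optional[frozenset[str]] = None,
) -> bool:
    """Effective-reference-size filter for one candidate signature.

    Counts solid-call samples in *valid* breeds that do not carry the
    signature; the candidate survives when that count reaches
    ``min_reference_n``.  Evaluated per candidate (per orientation).
    """
    if valid_breeds is None:
        valid_breeds = locus_valid_breeds(mask, cfg)
    carriers = set(carrier_breeds)
    n_ref = sum(
        mask.breed_solid_n[b] for b in valid_breeds if b not in carriers
    )
    return n_ref >= cfg.min_reference_n


def reference_solid_count(
    carrier_breeds: Iterable[str],
    mask: SolidCallMask,
    valid_breeds: frozenset[str],
) -> int:
    carriers = set(carrier_breeds)
    return sum(mask.breed_solid_n[b] for b in valid_breeds if b not in carriers)
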