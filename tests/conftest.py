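"""Shared fixtures: a scaled config, a seeded synthetic cohort and builders
for small in-memory loci."""

from __future__ import annotations

import numpy as np
import pytest

from breedsig import ThresholdConfig
from breedsig.engine import scan_cohort
from breedsig.io import BreedPanel, VariantLocus, read_breed_panel
from breedsig.simulate import CohortDesign, simulate_cohort

#: genotype shorthand used by the locus builders
GT = {"RR": (0, 0), "RA": (0, 1), "AA": (1, 1), "..": None}


def make_panel(breed_sizes: dict[str, int]) -> BreedPanel:
    return BreedPanel(
        {
            f"{breed}_{i}": breed
            for breed in breed_sizes
            for i in range(breed_sizes[breed])
        }
    )


def make_locus(
    codes,
    chrom="chr1",
    pos=1000,
    ref="A",
    alts=("G",),
    depth=20,
    depths=None,
    annotations=(),
):
    """Bi-/multi-allelic locus from per-sample genotype codes or index pairs.

    ``codes`` entries may be "RR"/"RA"/"AA"/".." shorthands or explicit
    allele-index pairs; ``depths`` (optional) gives per-sample total depths.
    """
    gts = [GT[c] if isinstance(c, str) else c for c in codes]
    n_alleles = 1 + len(alts)
    ads = []
    for i, gt in enumerate(gts):
        total = depth if depths is None else depths[i]
        if total is None or gt is None:
            ads.append(None if total is None else tuple([total] + [0] * len(alts)))
            continue
        ad = [0] * n_alleles
        a, b = gt
        if a == b:
            ad[a] = total
        else:
            ad[a] = total - total // 2
            ad[b] = total // 2
        ads.append(tuple(ad))
    return VariantLocus(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        genotypes=gts,
        allele_depths=ads,
        annotations=list(annotations),
    )


@pytest.fixture(scope="session")
def cfg() -> ThresholdConfig:
    """Default thresholds with the reference filter scaled to a 40-dog cohort."""
    return ThresholdConfig(min_reference_n=20)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Seeded synthetic cohort: (vcf path, panel path, truth table, panel)."""
    out = tmp_path_factory.mktemp("cohort")
    vcf, panel_path, truth = simulate_cohort(CohortDesign(), seed=7, out_dir=out)
    return vcf, panel_path, truth, read_breed_panel(panel_path)


@pytest.fixture(scope="session")
def catalogs(cohort, cfg):
    vcf, _, _, panel = cohort
    return scan_cohort(vcf, panel, cfg)


def truth_keys(truth, flag):
    """(chrom, pos, orientation, carriers) keys of truth rows with a flag set."""
    sub = truth[truth[flag]]
    return {
        (t.chrom, int(t.pos), t.orientation, ",".join(sorted(t.carriers.split(","))))
        for t in sub.itertuples()
    }


def record_keys(records):
    return {
        (r.chrom, r.pos, r.orientation.value, ",".join(sorted(r.carrier_breeds)))
        for r in records
    }
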