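"""Breed relatedness from shared signatures and per-dog breed composition.

A signature carried by k breeds counts toward all k breeds and all k-choose-2
breed pairs.  Pairwise similarity divides the shared count by the geometric
mean of the two breeds' own counts; a min-max standardised score over the
off-diagonal entries is reported alongside.  Individual dogs are profiled by
their mean carry score (0 / 0.5 / 1 per locus) over each breed's signature
catalog.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ThresholdConfig
from .engine import Orientation, SignatureRecord
from .io import BreedPanel, stream_variants
from .qc import is_solid_call
from .str_typing import STRGroupCall, decompose_str_locus, sample_group_call

__all__ = [
    "count_shared_signatures",
    "similarity_matrix",
    "correlate_score_vectors",
    "carry_score",
    "infer_breed_composition",
]


def count_shared_signatures(
    gs: Iterable[SignatureRecord], breeds: Sequence[str]
) -> pd.DataFrame:
    """Symmetric sharing-count matrix N.

    ``N[i, i]`` is breed i's signature count; ``N[i, j]`` the number of
    signatures carried by both i and j.
    """
    breeds = list(breeds)
    idx = {b: i for i, b in enumerate(breeds)}
    n = np.zeros((len(breeds), len(breeds)), dtype=int)
    for rec in gs:
        members = [idx[b] for b in rec.carrier_breeds if b in idx]
        for i in members:
            n[i, i] += 1
        for i, j in combinations(sorted(members), 2):
            n[i, j] += 1
            n[j, i] += 1
    return pd.DataFrame(n, index=breeds, columns=breeds)


def similarity_matrix(
    n: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Geometric-mean similarity s and its min-max standardisation z.

    ``s[i, j] = N[i, j] / sqrt(N[i, i] * N[j, j])``; breeds with zero
    signatures get NA rows/columns.  z rescales the off-diagonal entries of s
    so the largest becomes 1 and the smallest 0; if all off-diagonal values
    coincide z is NA with a warning.
    """
    diag = np.diag(n.to_numpy()).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(diag, diag))
        s = n.to_numpy(dtype=float) / denom
    s[:, diag == 0] = np.nan
    s[diag == 0, :] = np.nan
    s_df = pd.DataFrame(s, index=n.index, columns=n.columns)

    off = ~np.eye(len(n), dtype=bool)
    vals = s[off]
    vals = vals[~np.isnan(vals)]
    z = np.full_like(s, np.nan)
    if vals.size and vals.max() > vals.min():
        z[off] = (s[off] - vals.min()) / (vals.max() - vals.min())
    else:
        warnings.warn(
            "all off-diagonal similarity values identical; "
            "standardised scores undefined"
        )
    z_df = pd.DataFrame(z, index=n.index, columns=n.columns)
    return s_df, z_df


def correlate_score_vectors(
    a: Sequence[float], b: Sequence[float], method: str = "spearman"
) -> float:
    """Spearman rank or Pearson linear correlation of two aligned vectors.

    Returns NaN (with a warning) for constant vectors or length < 3.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be aligned on the same pairs")
    if a.size < 3 or np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("correlation undefined (constant vector or n < 3)")
        return float("nan")
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(sps.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def carry_score(
    genotype: Optional[tuple[int, int]],
    orientation: Orientation,
    group_call: Optional[STRGroupCall] = None,
) -> float:
    """Per-locus signature carry score: 1 homozygous-oriented, 0.5 het, 0 else.

    For STR orientations the score is driven by the repeat-group call
    (HIGH/LOW -> 1/0 for the matching orientation, MIXED -> 0.5).
    """
    if orientation in (Orientation.STR_HIGH, Orientation.STR_LOW):
        if group_call is None or group_call is STRGroupCall.NO_CALL:
            return 0.0
        if group_call is STRGroupCall.MIXED:
            return 0.5
        matches = (group_call is STRGroupCall.HIGH) == (
            orientation is Orientation.STR_HIGH
        )
        return 1.0 if matches else 0.0
    if genotype is None:
        return 0.0
    target = 1 if orientation is Orientation.VARIANT else 0
    hits = sum(1 for a in genotype if a == target)
    return hits / 2.0


def infer_breed_composition(
    vcf_path,
    samples: Sequence[str],
    catalog: Sequence[SignatureRecord],
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """Per-sample breed-composition fractions over the signature catalog.

    For each breed the fraction is the summed carry score over the breed's
    signature loci divided by the breed's total signature count; loci where
    the sample has no solid call score 0 but stay in the denominator.  Breeds
    without signatures are reported NA.  Returns a samples x breeds frame.
    """
    panel = BreedPanel({s: "query" for s in samples})
    by_locus: dict[tuple[str, int], list[SignatureRecord]] = {}
    breed_totals: dict[str, int] = {}
    for rec in catalog:
        by_locus.setdefault((rec.chrom, rec.pos), []).append(rec)
        for b in rec.carrier_breeds:
            breed_totals[b] = breed_totals.get(b, 0) + 1
    breeds = sorted(breed_totals)
    sums = pd.DataFrame(0.0, index=list(samples), columns=breeds)

    for locus in stream_variants(vcf_path, panel):
        recs = by_locus.get((locus.chrom, locus.pos))
        if not recs:
            continue
        model = None
        calls = None
        if any(
            r.orientation in (Orientation.STR_HIGH, Orientation.STR_LOW)
            for r in recs
        ):
            model = decompose_str_locus(
                locus.alleles, cfg, chrom=locus.chrom, pos=locus.pos
            )
            if model is not None:
                calls = [
                    sample_group_call(gt, ad, model, locus.chrom, cfg)
                    for gt, ad in zip(locus.genotypes, locus.allele_depths)
                ]
        for i, sample in enumerate(panel.samples):
            gt = locus.genotypes[i]
            ad = locus.allele_depths[i]
            solid = is_solid_call(gt, ad, locus.chrom, cfg)
            for rec in recs:
                if rec.orientation in (
                    Orientation.STR_HIGH,
                    Orientation.STR_LOW,
                ):
                    score = (
                        carry_score(
                            gt, rec.orientation, group_call=calls[i]
                        )
                        if calls is not None
                        else 0.0
                    )
                else:
                    score = carry_score(gt, rec.orientation) if solid else 0.0
                for b in rec.carrier_breeds:
                    sums.loc[sample, b] += score

    for b in breeds:
        sums[b] /= breed_totals[b]
    return sums


def rank_composition(row: pd.Series, top: int = 5) -> pd.DataFrame:
    """Ranked breed list for one sample with top/bottom convenience flags."""
    ordered = row.sort_values(ascending=False)
    df = pd.DataFrame(
        {"breed": ordered.index, "fraction": ordered.to_numpy()}
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["flag"] = ""
    df.loc[df.index[:top], "flag"] = "top"
    df.loc[df.index[-top:], "flag"] = df.loc[df.index[-top:], "flag"].where(
        df.loc[df.index[-top:], "flag"] != "", "bottom"
    )
    return df
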