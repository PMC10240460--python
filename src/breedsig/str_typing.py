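"""Short-tandem-repeat typing of multi-allelic INDEL loci.

A locus enters STR detection when it is multi-allelic and its alleles differ
in length.  It is accepted as an STR when every allele decomposes as a shared
anchor, an integer number of copies of one primitive 1-6 bp repeat unit, and
an optional shared suffix (the caller's right flank).  Accepted loci get
their distinct repeat counts split into a low- and a high-repeat group by
one-dimensional two-centroid K-means seeded with the minimum and maximum
counts — the boundary the published protocol uses to call expansion and
contraction alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .config import ThresholdConfig
from .qc import effective_depth

__all__ = [
    "STRLocusModel",
    "STRGroupCall",
    "decompose_str_locus",
    "allele_repeat_count",
    "split_repeat_groups",
    "sample_group_call",
    "primitive_root",
]


def primitive_root(unit: str) -> str:
    """Shortest string whose repetition produces ``unit`` ("ATAT" -> "AT")."""
    n = len(unit)
    for d in range(1, n + 1):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return unit[:d]
    return unit  # pragma: no cover


@dataclass(frozen=True)
class STRLocusModel:
    """Decomposition of one locus: ``allele = anchor + unit*k + suffix``.

    ``repeat_counts`` aligns with the allele order given to
    :func:`decompose_str_locus` (ref first, by convention of the caller).
    ``low_group``/``high_group`` partition the *distinct* counts; ``boundary``
    is the midpoint of the two final K-means centroids.
    """

    anchor: str
    unit: str
    suffix: str
    repeat_counts: tuple[int, ...]
    low_group: frozenset[int]
    high_group: frozenset[int]
    boundary: float
    chrom: str = ""
    pos: int = 0

    @property
    def group_spread(self) -> tuple[int, int]:
        return (max(self.low_group), min(self.high_group))

    @property
    def unit_diff(self) -> int:
        """Repeat-count gap between the groups: min(high) - max(low)."""
        return min(self.high_group) - max(self.low_group)

    def range_notation(self, counts: Iterable[int]) -> str:
        """Allele-range notation, e.g. ``A(TTCT)0-3``."""
        cs = sorted(set(counts))
        span = f"{cs[0]}" if len(cs) == 1 else f"{cs[0]}-{cs[-1]}"
        return f"{self.anchor}({self.unit}){span}"


class STRGroupCall(Enum):
    LOW = "LOW"
    HIGH = "HIGH"
    MIXED = "MIXED"
    NO_CALL = "NO_CALL"


def _decompose_middles(middles: Sequence[str], unit_len: int) -> Optional[list[int]]:
    """Repeat counts if every middle is ``u**k`` for one unit of ``unit_len``."""
    unit = None
    for m in middles:
        if len(m) % unit_len:
            return None
        if m and unit is None:
            unit = m[:unit_len]
    if unit is None:
        return None
    counts = []
    for m in middles:
        k = len(m) // unit_len
        if unit * k != m:
            return None
        counts.append(k)
    return counts


def decompose_str_locus(
    alleles: Sequence[str],
    cfg: ThresholdConfig,
    chrom: str = "",
    pos: int = 0,
) -> Optional[STRLocusModel]:
    """Fit a single-repeat-unit model to a multi-allelic locus, or reject.

    Searches for the shortest primitive unit (preferring, at equal unit
    length, the longest common anchor and shortest residual suffix) such that
    every allele is ``anchor + unit*k + suffix`` with k varying across
    alleles.  Loci whose alleles need more than one unit type are rejected
    (returns None); rejection is an expected outcome, not an error.
    """
    if len(set(alleles)) < 3:
        return None
    if any(not a for a in alleles):
        return None
    min_len = min(len(a) for a in alleles)
    # longest shared prefix length
    max_anchor = 0
    while max_anchor < min_len and len({a[max_anchor] for a in alleles}) == 1:
        max_anchor += 1
    for unit_len in range(cfg.unit_len_min, cfg.unit_len_max + 1):
        for anchor_len in range(max_anchor, -1, -1):
            max_suffix = min(len(a) for a in alleles) - anchor_len
            for suffix_len in range(0, max_suffix + 1):
                if suffix_len and len(
                    {a[len(a) - suffix_len :] for a in alleles}
                ) != 1:
                    break  # a longer shared suffix cannot exist either
                middles = [a[anchor_len : len(a) - suffix_len] for a in alleles]
                counts = _decompose_middles(middles, unit_len)
                if counts is None or len(set(counts)) < 2:
                    continue
                unit = next(
                    m[:unit_len] for m in middles if m
                )
                if primitive_root(unit) != unit:
                    continue
                low, high, boundary = split_repeat_groups(counts)
                return STRLocusModel(
                    anchor=alleles[0][:anchor_len],
                    unit=unit,
                    suffix=alleles[0][len(alleles[0]) - suffix_len :]
                    if suffix_len
                    else "",
                    repeat_counts=tuple(counts),
                    low_group=low,
                    high_group=high,
                    boundary=boundary,
                    chrom=chrom,
                    pos=pos,
                )
    return None


def allele_repeat_count(allele: str, model: STRLocusModel) -> int:
    """Exponent k in ``allele = anchor + unit*k + suffix``."""
    core = allele
    if model.anchor:
        if not core.startswith(model.anchor):
            raise ValueError(f"allele {allele!r} lacks anchor {model.anchor!r}")
        core = core[len(model.anchor) :]
    if model.suffix:
        if not core.endswith(model.suffix):
            raise ValueError(f"allele {allele!r} lacks suffix {model.suffix!r}")
        core = core[: len(core) - len(model.suffix)]
    if len(core) % len(model.unit):
        raise ValueError(f"allele {allele!r} not a whole number of {model.unit!r}")
    k = len(core) // len(model.unit)
    if model.unit * k != core:
        raise ValueError(f"allele {allele!r} does not repeat {model.unit!r}")
    return k


def split_repeat_groups(
    counts: Iterable[int],
) -> tuple[frozenset[int], frozenset[int], float]:
    """Two-cluster 1-D K-means over distinct repeat counts.

    Lloyd iterations to convergence, seeded with the minimum and maximum
    counts; a point equidistant from both centroids joins the low group.
    Returns ``(low, high, boundary)`` where boundary is the final centroid
    midpoint.  Raises when fewer than two distinct counts exist.
    """
    xs = sorted(set(counts))
    if len(xs) < 2:
        raise ValueError("need at least two distinct repeat counts to split")
    c_lo, c_hi = float(xs[0]), float(xs[-1])
    while True:
        low = [x for x in xs if abs(x - c_lo) <= abs(x - c_hi)]
        high = [x for x in xs if abs(x - c_lo) > abs(x - c_hi)]
        if not high:  # degenerate seeding cannot occur with distinct min/max
            high = [low.pop()]  # pragma: no cover
        new_lo = sum(low) / len(low)
        new_hi = sum(high) / len(high)
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    return frozenset(low), frozenset(high), (c_lo + c_hi) / 2.0


def sample_group_call(
    genotype: Optional[tuple[int, int]],
    depths: Optional[tuple[int, ...]],
    model: STRLocusModel,
    chrom: str,
    cfg: ThresholdConfig,
) -> STRGroupCall:
    """Classify one dog's genotype into LOW/HIGH/MIXED/NO_CALL.

    The effective depth is the summed AD of the final called allele types;
    below the chromosome-class threshold (or with a missing genotype) the
    sample is NO_CALL and drops out of both numerator and denominator.
    """
    d = effective_depth(genotype, depths)
    if d is None or d < cfg.depth_threshold(chrom):
        return STRGroupCall.NO_CALL
    ka, kb = (model.repeat_counts[a] for a in genotype)
    in_low = {ka in model.low_group, kb in model.low_group}
    if in_low == {True}:
        return STRGroupCall.LOW
    if in_low == {False}:
        return STRGroupCall.HIGH
    return STRGroupCall.MIXED
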