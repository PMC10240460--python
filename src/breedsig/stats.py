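"""Effect-category tabulation and the exact 2x2 enrichment test.

The coding/non-coding split drives the headline comparison between variant
types (e.g. the fraction of breed-specific INDELs in coding sequence versus
that of breed-specific SNPs).  The two-sided Fisher test follows the exact
convention — the sum of hypergeometric point probabilities no larger than the
observed table's — computed in integer arithmetic, so tied tables are handled
without floating-point tolerance.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import pandas as pd

from .config import ThresholdConfig
from .engine import SignatureRecord

__all__ = [
    "round_half_up",
    "percentage",
    "tabulate_effect_categories",
    "fisher_exact_two_sided",
]

#: Functional classes summarised alongside the coding/non-coding split.
FUNCTIONAL_CLASSES = {
    "missense": ("missense_variant",),
    "nonsense": ("stop_gained",),
    "frameshift": ("frameshift_variant",),
    "inframe": (
        "disruptive_inframe_deletion",
        "disruptive_inframe_insertion",
        "conservative_inframe_deletion",
        "conservative_inframe_insertion",
    ),
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (1.0738 -> 1.07, 99.905 -> 99.91)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(num: int, den: int, ndigits: int = 2) -> float:
    """Exact percentage with half-up rounding at ``ndigits`` decimals."""
    if den == 0:
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(
        (Decimal(num) * 100 / Decimal(den)).quantize(q, rounding=ROUND_HALF_UP)
    )


def tabulate_effect_categories(
    records: Iterable[SignatureRecord], cfg: ThresholdConfig
) -> pd.DataFrame:
    """Per (breed, variant type) coding/non-coding and functional-class counts.

    A record is *coding* when any of its effect terms belongs to the
    configured coding-term set.  Percentages are half-up rounded to two
    decimals.  Empty input yields an empty frame.
    """
    rows: dict[tuple[str, str], dict] = {}
    for rec in records:
        terms = set(rec.effect_terms)
        coding = bool(terms & cfg.coding_terms)
        for breed in sorted(rec.carrier_breeds):
            key = (breed, rec.variant_type.value)
            row = rows.setdefault(
                key,
                {
                    "breed": breed,
                    "variant_type": rec.variant_type.value,
                    "n_total": 0,
                    "n_coding": 0,
                    "n_noncoding": 0,
                    **{f"n_{cls}": 0 for cls in FUNCTIONAL_CLASSES},
                    "n_other_functional": 0,
                },
            )
            row["n_total"] += 1
            row["n_coding" if coding else "n_noncoding"] += 1
            if coding:
                matched = False
                for cls, cls_terms in FUNCTIONAL_CLASSES.items():
                    if terms & set(cls_terms):
                        row[f"n_{cls}"] += 1
                        matched = True
                if not matched:
                    row["n_other_functional"] += 1
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["breed"], r["variant_type"])))
    df["pct_coding"] = [
        percentage(c, t) for c, t in zip(df["n_coding"], df["n_total"])
    ]
    df["pct_noncoding"] = [
        percentage(c, t) for c, t in zip(df["n_noncoding"], df["n_total"])
    ]
    return df


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p for a 2x2 table.

    p is the sum, over all tables with the observed margins, of the
    hypergeometric point probabilities that do not exceed the observed
    table's.  Computed with exact integer binomials; degenerate margins (a
    zero row or column) give p = 1.  The result lies in (0, 1].
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(lo, hi + 1):
        weight = comb(r1, x) * comb(r2, c1 - x)
        if weight <= observed:
            total += weight
    return float(Fraction(total, comb(n, c1)))
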