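"""Threshold configuration shared by every stage of the discovery pipeline.

All cutoffs the scans depend on live in one frozen dataclass so that a run is
fully described by its config.  Defaults mirror the published protocol for a
~400-dog multi-breed cohort; ``min_reference_n`` in particular must be scaled
down for small cohorts (it is a count of solid reference samples, not a
fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

#: SnpEff-style effect terms flagged as protein-changing ("functional") on
#: breed-specific signatures.
DEFAULT_FUNCTIONAL_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "frameshift_variant",
        "disruptive_inframe_deletion",
        "disruptive_inframe_insertion",
        "conservative_inframe_deletion",
        "conservative_inframe_insertion",
    }
)

#: Effect terms counted as "coding" in the coding/non-coding tabulation.
DEFAULT_CODING_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "synonymous_variant",
        "frameshift_variant",
        "disruptive_inframe_deletion",
        "disruptive_inframe_insertion",
        "conservative_inframe_deletion",
        "conservative_inframe_insertion",
        "coding_sequence_variant",
    }
)


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable thresholds of the signature discovery engine.

    Attributes
    ----------
    bvf_high, bvf_low
        Breed-variant-frequency cutoffs: a breed "carries" an oriented allele
        state when BVF >= ``bvf_high`` (inclusive); breed-specific exclusivity
        requires every other valid breed at BVF <= ``bvf_low`` (inclusive).
    min_breed_n
        Minimum solid-call dogs for a breed to be *valid* at a locus.
    min_reference_n
        Minimum solid-call samples across valid non-carrier breeds for a
        candidate signature to be retained.
    depth_autosome, depth_x
        Per-sample minimum summed depth of the called allele types.
    max_short_indel
        Exclusive upper bound (bp) on ref/alt length difference for an INDEL
        to be reported as a breed-specific short INDEL.
    hotspot_min, stretch_min, stretch_density, structure_gap, structure_min
        Segment-detection parameters: gene hotspots need >= ``hotspot_min``
        BSGS; density stretches need >= ``stretch_min`` BSGS at
        >= ``stretch_density`` per kb; breed-specific structures allow
        inter-BSGS gaps <= ``structure_gap`` bp and need >= ``structure_min``
        members.
    block_size, block_high
        Genome tiling block length (bp) and the "high signature count" block
        threshold.
    unit_len_min, unit_len_max
        Allowed STR repeat-unit lengths (bp).
    repeat_diff_report
        Repeat-unit difference (carrier vs reference group) at which an STR
        signature is flagged as a large expansion/contraction.
    """

    bvf_high: float = 0.9
    bvf_low: float = 0.1
    min_breed_n: int = 3
    min_reference_n: int = 300
    depth_autosome: int = 10
    depth_x: int = 5
    max_short_indel: int = 10
    hotspot_min: int = 5
    stretch_min: int = 10
    stretch_density: float = 10.0
    structure_gap: int = 100_000
    structure_min: int = 10
    block_size: int = 10_000
    block_high: int = 40
    unit_len_min: int = 1
    unit_len_max: int = 6
    repeat_diff_report: int = 3
    x_chrom_names: frozenset = frozenset({"chrX", "X"})
    par_chrom: str = "chrX"
    par_start: int = 0
    par_end: int = 6_600_000
    functional_terms: frozenset = DEFAULT_FUNCTIONAL_TERMS
    coding_terms: frozenset = DEFAULT_CODING_TERMS

    def __post_init__(self) -> None:
        if not (0.0 <= self.bvf_low < self.bvf_high <= 1.0):
            raise ValueError(
                f"require 0 <= bvf_low < bvf_high <= 1, got "
                f"low={self.bvf_low} high={self.bvf_high}"
            )
        for name in (
            "min_breed_n",
            "min_reference_n",
            "depth_autosome",
            "depth_x",
            "max_short_indel",
            "hotspot_min",
            "stretch_min",
            "structure_gap",
            "structure_min",
            "block_size",
            "block_high",
            "repeat_diff_report",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.unit_len_min <= self.unit_len_max <= 6):
            raise ValueError("unit length range must lie within [1, 6]")

    # -- helpers -----------------------------------------------------------

    def depth_threshold(self, chrom: str) -> int:
        """Per-sample depth cutoff for a chromosome (X vs autosome)."""
        return self.depth_x if chrom in self.x_chrom_names else self.depth_autosome

    def is_functional(self, effect_terms: Iterable[str]) -> bool:
        return any(t in self.functional_terms for t in effect_terms)

    def replace(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **kwargs)

    # -- flat key-value config file ---------------------------------------

    _SET_FIELDS = ("x_chrom_names", "functional_terms", "coding_terms")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ThresholdConfig":
        kwargs: dict = {}
        known = {f.name: f for f in fields(cls)}
        for key, raw in mapping.items():
            if key not in known:
                raise KeyError(f"unknown config key: {key!r}")
            if key in cls._SET_FIELDS:
                kwargs[key] = frozenset(
                    tok.strip() for tok in str(raw).split(",") if tok.strip()
                )
            else:
                default = getattr(cls, key)
                if isinstance(default, bool):
                    kwargs[key] = str(raw).lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "ThresholdConfig":
        """Read a flat ``key = value`` config file (# comments allowed)."""
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
            elif "\t" in line:
                key, _, value = line.partition("\t")
            else:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            mapping[key.strip()] = value.strip()
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = sorted(v) if isinstance(v, frozenset) else v
        return out
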