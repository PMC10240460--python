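"""BVF computation, universal exclusion, GS/BSGS/pair/STR scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedsig import ThresholdConfig
from breedsig.engine import (
    BSGSRecord,
    Orientation,
    STRSignatureType,
    VariantType,
    compute_bvf,
    is_universal_variant,
    scan_bsgs,
    scan_gs,
    scan_locus,
    scan_pair_signatures,
)
from breedsig.qc import solid_call_mask

from conftest import make_locus, make_panel, record_keys, truth_keys

# a 40-dog cohort needs only 20 solid reference samples
CFG = ThresholdConfig(min_reference_n=5)


def bvf_of(locus, panel, orientation=Orientation.VARIANT, cfg=CFG):
    mask = solid_call_mask(locus, panel, cfg)
    return compute_bvf(locus, orientation, panel, mask, cfg), mask


class TestBVF:
    def test_fixed_breed_has_bvf_one(self):
        panel = make_panel({"A": 4, "B": 4})
        locus = make_locus(["AA"] * 4 + ["RR"] * 4)
        bvf, _ = bvf_of(locus, panel)
        assert bvf.bvf("A") == 1.0
        assert bvf.bvf("B") == 0.0

    def test_heterozygotes_count_in_denominator_only(self):
        panel = make_panel({"A": 5})
        locus = make_locus(["AA", "AA", "AA", "RA", "RR"])
        bvf, _ = bvf_of(locus, panel)
        assert bvf.bvf("A") == pytest.approx(0.6)

    def test_invalid_breed_absent_from_record(self):
        panel = make_panel({"A": 5, "B": 5})
        locus = make_locus(
            ["AA"] * 5 + ["AA"] * 5,
            depths=[20] * 5 + [20, 20, 3, 3, 3],
        )
        bvf, _ = bvf_of(locus, panel)
        assert "B" not in bvf.per_breed
        assert "A" in bvf.per_breed

    def test_orientation_class_mismatch_is_error(self):
        panel = make_panel({"A": 3})
        locus = make_locus([(0, 0)] * 3, alts=("AT", "ATT"))
        mask = solid_call_mask(locus, panel, CFG)
        with pytest.raises(ValueError):
            compute_bvf(locus, Orientation.VARIANT, panel, mask, CFG)


class TestUniversal:
    def test_all_hom_alt_is_universal(self):
        panel = make_panel({"A": 3, "B": 3})
        bvf, _ = bvf_of(make_locus(["AA"] * 6), panel)
        assert is_universal_variant(bvf)

    def test_one_het_breaks_universality(self):
        panel = make_panel({"A": 3, "B": 3})
        bvf, _ = bvf_of(make_locus(["AA"] * 5 + ["RA"]), panel)
        assert not is_universal_variant(bvf)

    def test_no_solid_dogs_warns_and_is_false(self):
        panel = make_panel({"A": 3})
        bvf, _ = bvf_of(make_locus(["AA"] * 3, depths=[1, 1, 1]), panel)
        with pytest.warns(UserWarning):
            assert not is_universal_variant(bvf)


class TestScans:
    def test_gs_threshold_is_inclusive(self):
        panel = make_panel({"A": 10, "B": 10})
        locus = make_locus(["AA"] * 9 + ["RR"] + ["RR"] * 10)
        bvf, mask = bvf_of(locus, panel)
        rec = scan_gs(locus, bvf, mask, CFG, VariantType.SNP)
        assert rec is not None and rec.carrier_breeds == {"A"}
        # 8/10 = 0.8 < 0.9: no signature
        locus2 = make_locus(["AA"] * 8 + ["RR"] * 2 + ["RR"] * 10)
        bvf2, mask2 = bvf_of(locus2, panel)
        assert scan_gs(locus2, bvf2, mask2, CFG, VariantType.SNP) is None

    def test_multi_carrier_gs_is_one_record(self):
        panel = make_panel({"A": 3, "B": 3, "C": 3, "D": 5})
        locus = make_locus(["AA"] * 9 + ["RR", "RA", "RR", "RR", "RA"])
        bvf, mask = bvf_of(locus, panel)
        rec = scan_gs(locus, bvf, mask, CFG, VariantType.SNP)
        assert rec.carrier_breeds == {"A", "B", "C"}
        assert rec.n_reference_solid == 5

    def test_bsgs_ideal_and_exclusivity_violation(self):
        panel = make_panel({"A": 5, "B": 5, "C": 5})
        ideal = make_locus(["AA"] * 5 + ["RR"] * 10)
        bvf, mask = bvf_of(ideal, panel)
        rec = scan_bsgs(ideal, bvf, mask, CFG, VariantType.SNP)
        assert isinstance(rec, BSGSRecord) and rec.breed == "A"
        # a second breed at 0.2 > bvf_low breaks exclusivity
        leaky = make_locus(["AA"] * 5 + ["AA", "RR", "RR", "RR", "RR"] + ["RR"] * 5)
        bvf2, mask2 = bvf_of(leaky, panel)
        assert scan_bsgs(leaky, bvf2, mask2, CFG, VariantType.SNP) is None

    def test_short_indel_size_rule_applies_to_bsgs_only(self):
        panel = make_panel({"A": 5, "B": 5})
        locus = make_locus(["AA"] * 5 + ["RR"] * 5, ref="A", alts=("A" + "T" * 12,))
        bvf, mask = bvf_of(locus, panel)
        assert scan_bsgs(locus, bvf, mask, CFG, VariantType.INDEL) is None
        assert scan_gs(locus, bvf, mask, CFG, VariantType.INDEL) is not None

    def test_pair_requires_exactly_two_carriers(self):
        panel = make_panel({"A": 3, "B": 3, "C": 3, "D": 3})
        two = make_locus(["AA"] * 6 + ["RR"] * 6)
        bvf, mask = bvf_of(two, panel)
        pair, rec = scan_pair_signatures(two, bvf, mask, CFG, VariantType.SNP)
        assert pair == ("A", "B")
        three = make_locus(["AA"] * 9 + ["RR"] * 3)
        bvf3, mask3 = bvf_of(three, panel)
        assert scan_pair_signatures(three, bvf3, mask3, CFG, VariantType.SNP) is None

    def test_reference_orientation_symmetry(self):
        """A breed fixed hom-ref while others are fixed hom-alt yields a
        REFERENCE-orientation breed-specific record."""
        panel = make_panel({"A": 5, "B": 5, "C": 5})
        locus = make_locus(["RR"] * 5 + ["AA"] * 10)
        result = scan_locus(locus, panel, CFG)
        assert len(result.bsgs) == 1
        rec = result.bsgs[0]
        assert rec.orientation is Orientation.REFERENCE
        assert rec.breed == "A"

    def test_universal_locus_yields_nothing(self):
        panel = make_panel({"A": 5, "B": 5})
        locus = make_locus(["AA"] * 10)
        result = scan_locus(locus, panel, CFG)
        assert not result.gs and not result.bsgs and not result.pairs


class TestSTRScan:
    def _locus(self, carrier_codes, other_codes):
        alleles = ("A", "ATTCT", "A" + "TTCT" * 2, "A" + "TTCT" * 3,
                   "A" + "TTCT" * 8, "A" + "TTCT" * 9, "A" + "TTCT" * 10)
        codes = carrier_codes + other_codes
        return make_locus(
            codes, ref=alleles[0], alts=alleles[1:], depth=30
        )

    def test_expansion_with_unit_diff_flag(self):
        panel = make_panel({"A": 5, "B": 5, "C": 5})
        carrier = [(4, 4), (5, 5), (6, 6), (4, 5), (6, 6)]  # counts 8-10
        others = [(0, 0), (1, 1), (2, 2), (3, 3), (0, 1)] * 2  # counts 0-3
        result = scan_locus(self._locus(carrier, others), panel, CFG)
        assert len(result.bsgs) == 1
        rec = result.bsgs[0]
        assert rec.signature_type is STRSignatureType.EXPANSION
        assert rec.unit == "TTCT"
        assert rec.unit_diff == 5
        assert rec.large_repeat_diff
        assert rec.carrier_repeat_range == "A(TTCT)8-10"
        assert rec.reference_repeat_range == "A(TTCT)0-3"

    def test_contraction_labelling(self):
        panel = make_panel({"A": 5, "B": 5, "C": 5})
        carrier = [(0, 0)] * 5
        others = [(4, 4), (5, 5), (6, 6), (4, 4), (5, 6)] * 2
        result = scan_locus(self._locus(carrier, others), panel, CFG)
        recs = [r for r in result.bsgs]
        assert len(recs) == 1
        assert recs[0].signature_type is STRSignatureType.CONTRACTION

    def test_one_mixed_dog_drops_below_threshold(self):
        panel = make_panel({"A": 5, "B": 5, "C": 5})
        carrier = [(4, 4), (5, 5), (6, 6), (4, 5), (0, 6)]  # last dog MIXED
        others = [(0, 0), (1, 1), (2, 2), (3, 3), (0, 1)] * 2
        result = scan_locus(self._locus(carrier, others), panel, CFG)
        assert result.bsgs == []


class TestInvariantsOnCohort:
    def test_bsgs_subset_of_gs(self, catalogs):
        gs_keys = record_keys(catalogs.gs)
        assert record_keys(catalogs.bsgs_all()) <= gs_keys

    def test_planted_truth_recovered(self, cohort, catalogs):
        _, _, truth, _ = cohort
        assert record_keys(catalogs.gs) == truth_keys(truth, "expect_gs")
        assert record_keys(catalogs.bsgs_all()) == truth_keys(truth, "expect_bsgs")


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    codes=st.lists(
        st.sampled_from(["RR", "RA", "AA"]), min_size=12, max_size=12
    ),
    d_high=st.floats(min_value=0.5, max_value=1.0),
    d_low=st.floats(min_value=0.0, max_value=0.45),
)
def test_orientation_duality_and_threshold_monotonicity(codes, d_high, d_low):
    """Relabelling ref<->alt maps VARIANT results onto REFERENCE results, and
    stricter thresholds never add signatures."""
    panel = make_panel({"A": 4, "B": 4, "C": 4})
    cfg = ThresholdConfig(bvf_high=0.9, bvf_low=0.1, min_reference_n=4)
    locus = make_locus(codes)
    flipped = make_locus([{"RR": "AA", "RA": "RA", "AA": "RR"}[c] for c in codes])

    res = scan_locus(locus, panel, cfg)
    res_f = scan_locus(flipped, panel, cfg)
    by_orient = lambda rs, o: {
        frozenset(r.carrier_breeds) for r in rs if r.orientation is o
    }
    assert by_orient(res.gs, Orientation.VARIANT) == by_orient(
        res_f.gs, Orientation.REFERENCE
    )
    assert by_orient(res.gs, Orientation.REFERENCE) == by_orient(
        res_f.gs, Orientation.VARIANT
    )

    strict = ThresholdConfig(
        bvf_high=max(cfg.bvf_high, d_high),
        bvf_low=min(cfg.bvf_low, d_low),
        min_reference_n=4,
    )
    res_strict = scan_locus(locus, panel, strict)
    assert record_keys(res_strict.gs) <= record_keys(res.gs)
    assert record_keys(res_strict.bsgs) <= record_keys(res.bsgs)
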