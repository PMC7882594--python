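"""Missense evidence layers: conservation boundaries, predictor
consensus arithmetic, intolerance screening, and track-level filtering
on cohorts with planted ground truth."""

import pytest
from hypothesis import given, strategies as st

from conftest import profile
from famseq.missense_track import (
    ConsensusRule,
    ConservationGate,
    IntoleranceCutoffs,
    assess_intolerance,
    passes_conservation,
    predictor_consensus,
    prioritize_missense,
)
from famseq.model import DataError, PREDICTORS, VariantRecord
from famseq.synthetic_cohort import CohortSpec, generate_cohort


def calls(n_del, n_tol):
    names = list(PREDICTORS)
    return {names[i]: "deleterious" for i in range(n_del)} | \
        {names[n_del + i]: "tolerated" for i in range(n_tol)}


class TestConservation:
    def test_all_scores_clearly_above(self):
        assert passes_conservation(profile(gerp=4.1, phastcons=0.95,
                                           phylop=5.2))

    def test_boundary_operators(self):
        # PhyloP threshold is inclusive, GERP and PhastCons are strict
        assert passes_conservation(profile(gerp=2.1, phastcons=0.4,
                                           phylop=3.0))
        assert not passes_conservation(profile(gerp=2.0, phastcons=0.4,
                                               phylop=5.0))
        assert not passes_conservation(profile(gerp=2.1, phastcons=0.3,
                                               phylop=5.0))
        assert not passes_conservation(profile(gerp=2.1, phastcons=0.4,
                                               phylop=2.999))

    def test_only_present_scores_are_required(self):
        assert passes_conservation(profile(gerp=3.0))       # one present, passes
        assert not passes_conservation(profile(gerp=1.0, phylop=8.0))

    def test_all_missing_is_no_evidence(self):
        assert not passes_conservation(profile())


class TestConsensus:
    def test_fraction_and_pass(self):
        frac, ok = predictor_consensus(profile(predictor_calls=calls(8, 2)))
        assert frac == pytest.approx(0.8) and ok

    def test_exact_half_fails_strict_majority(self):
        frac, ok = predictor_consensus(profile(predictor_calls=calls(5, 5)))
        assert frac == pytest.approx(0.5) and not ok

    def test_too_few_calls_fails_even_if_unanimous(self):
        frac, ok = predictor_consensus(profile(predictor_calls=calls(3, 0)))
        assert frac == pytest.approx(1.0) and not ok

    def test_zero_calls(self):
        frac, ok = predictor_consensus(profile())
        assert frac == 0.0 and not ok

    @given(st.integers(0, 10))
    def test_fraction_invariant_to_order_and_missing(self, n_del):
        n_tol = 10 - n_del
        full = profile(predictor_calls=calls(n_del, n_tol))
        # drop two calls to "missing": fraction recomputed over non-missing
        reduced_calls = dict(list(calls(n_del, n_tol).items()))
        for name in list(reduced_calls)[:2]:
            del reduced_calls[name]
        reduced = profile(predictor_calls=reduced_calls)
        f_full, _ = predictor_consensus(full)
        f_red, _ = predictor_consensus(reduced)
        n_del_red = sum(1 for c in reduced_calls.values()
                        if c == "deleterious")
        assert f_full == pytest.approx(n_del / 10)
        assert f_red == pytest.approx(n_del_red / max(len(reduced_calls), 1)
                                      if reduced_calls else 0.0)


class TestIntolerance:
    def test_positive_z_flags(self):
        s = assess_intolerance("G1", profile(exac_z=3.2))
        assert s.intolerant_flag and s.exac_z == 3.2

    def test_tolerant_gene(self):
        s = assess_intolerance("G1", profile(
            exac_z=-1.0, intolerance_percentiles={
                "esp6500": 80, "exac": 80, "local": 80}))
        assert not s.intolerant_flag

    def test_low_percentile_flags(self):
        s = assess_intolerance("G1", profile(
            intolerance_percentiles={"local": 10.0}))
        assert s.intolerant_flag

    def test_all_missing_summary(self):
        s = assess_intolerance("G1", profile())
        assert not s.intolerant_flag
        assert s.exac_z is None and s.percentiles == {}


def _missense_record(i, prof, fam="F01"):
    return VariantRecord("chr1", 1000 + i, "A", "G", "missense", f"G{i}",
                         fam, {}, prof)


class TestPrioritize:
    def passing_profile(self):
        return profile(gerp=4.0, phastcons=0.9, phylop=5.0,
                       predictor_calls=calls(9, 1))

    def failing_profile(self):
        return profile(gerp=1.0, phastcons=0.9, phylop=5.0,
                       predictor_calls=calls(2, 8))

    def test_empty_input(self):
        assert prioritize_missense([]) == []

    def test_non_missense_rejected(self):
        rec = VariantRecord("chr1", 1, "A", "G", "stopgain", "G", "F01", {})
        with pytest.raises(DataError, match="non-missense"):
            prioritize_missense([rec])

    def test_hard_filter_equals_annotate_restriction(self):
        records = [_missense_record(i, self.passing_profile() if i % 2
                                    else self.failing_profile())
                   for i in range(10)]
        annotated = prioritize_missense(records, mode="annotate")
        hard = prioritize_missense(records, mode="hard_filter")
        assert [c.record.key for c in hard] == \
            [c.record.key for c in annotated if c.evidence.hard_pass]
        # every annotated row carries a complete evidence record
        for c in annotated:
            assert c.evidence.consensus_available == 10
            assert isinstance(c.evidence.conservation_pass, bool)

    def test_needs_review_stratum(self):
        rec = _missense_record(0, profile(gerp=4.0,
                                          predictor_calls=calls(3, 0)))
        (cand,) = prioritize_missense([rec], mode="annotate")
        assert cand.evidence.needs_review
        assert not cand.evidence.consensus_pass

    def test_output_sorted_and_input_order_irrelevant(self):
        records = [_missense_record(i, self.passing_profile())
                   for i in (5, 1, 3)]
        a = prioritize_missense(records)
        b = prioritize_missense(list(reversed(records)))
        assert [c.record.key for c in a] == [c.record.key for c in b]
        assert [c.record.pos for c in a] == sorted(c.record.pos for c in a)

    def test_tightening_thresholds_shrinks_output(self):
        records = [_missense_record(i, profile(
            gerp=2.0 + 0.5 * i, phastcons=0.5, phylop=4.0,
            predictor_calls=calls(5 + i % 6, 5 - i % 6))) for i in range(12)]
        loose = prioritize_missense(records, gate=ConservationGate(),
                                    rule=ConsensusRule())
        tight = prioritize_missense(
            records, gate=ConservationGate(gerp_min=3.5),
            rule=ConsensusRule(min_deleterious_fraction=0.7))
        assert {c.record.key for c in tight} <= {c.record.key for c in loose}

    def test_planted_variants_recovered_from_cohort(self, cohort1):
        """Planted passing-regime missense variants pass the track gates;
        failing-regime plants with a sabotaged track gate do not; any
        extra survivor is a background record whose evidence genuinely
        passes every gate."""
        missense = [r for r in cohort1.variants if r.consequence == "missense"]
        out = prioritize_missense(missense, mode="hard_filter")
        out_keys = {c.record.key for c in out}
        passing = set(cohort1.ground_truth.passing_keys())
        assert passing <= out_keys
        for planted in cohort1.ground_truth.planted_variants:
            if planted.regimes["conservation"] == "failing" or \
                    planted.regimes["consensus"] == "failing":
                assert planted.key not in out_keys
        for c in out:
            assert c.evidence.hard_pass

    def test_intolerance_filter_mode(self):
        rich = self.passing_profile()
        rich.exac_z = 4.0
        poor = self.passing_profile()
        poor.exac_z = -2.0
        records = [_missense_record(0, rich), _missense_record(1, poor)]
        out = prioritize_missense(records, cutoffs=IntoleranceCutoffs(),
                                  intolerance_filter=True)
        assert [c.record.pos for c in out] == [1000]
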