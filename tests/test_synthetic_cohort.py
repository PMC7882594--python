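"""Generator contracts: Mendelian transmission, planted-variant
construction guarantees, determinism, and the analytic null calibration."""

import numpy as np
import pytest

from famseq.core_filters import passes_cadd, passes_maf
from famseq.missense_track import passes_conservation, predictor_consensus
from famseq.model import DataError, Individual, Pedigree
from famseq.segregation import evaluate_segregation
from famseq.synthetic_cohort import (
    CohortSpec,
    generate_cohort,
    mendelian_drop,
    null_shared_gate_moments,
    p_cadd_pass,
    p_maf_pass,
    write_cohort,
)

SMALL = CohortSpec(n_families=6, background_variants=200, seed=3)


class TestMendelianDrop:
    def test_carrier_by_noncarrier_transmits_half(self):
        """10^4 children of a het x hom-ref couple: carrier fraction
        within the 0.5 +/- 0.015 binomial band."""
        parents = {"DAD": (None, None), "MOM": (None, None)}
        n = 10_000
        for i in range(n):
            parents[f"C{i}"] = ("DAD", "MOM")
        rng = np.random.default_rng(42)
        gts = mendelian_drop(parents, {"DAD": (1, 0), "MOM": (0, 0)}, rng)
        frac = sum(sum(gts[f"C{i}"]) > 0 for i in range(n)) / n
        assert abs(frac - 0.5) < 0.015

    def test_noncarrier_couple_yields_noncarriers(self):
        parents = {"DAD": (None, None), "MOM": (None, None),
                   "C1": ("DAD", "MOM"), "C2": ("DAD", "MOM")}
        gts = mendelian_drop(parents, {"DAD": (0, 0), "MOM": (0, 0)},
                             np.random.default_rng(0))
        assert gts["C1"] == (0, 0) and gts["C2"] == (0, 0)

    def test_three_generations_deterministic(self):
        ped = Pedigree([
            Individual("GF", "F", None, None, "male", "affected"),
            Individual("GM", "F", None, None, "female", "unaffected"),
            Individual("P1", "F", "GF", "GM", "male", "affected"),
            Individual("SP", "F", None, None, "female", "unaffected"),
            Individual("K1", "F", "P1", "SP", "female", "unknown"),
            Individual("K2", "F", "P1", "SP", "male", "unknown"),
        ])
        founders = {"GF": (1, 0), "GM": (0, 0), "SP": (0, 0)}
        a = mendelian_drop(ped, founders, np.random.default_rng(9))
        b = mendelian_drop(ped, founders, np.random.default_rng(9))
        assert a == b

    def test_missing_founder_genotype_is_error(self):
        with pytest.raises(DataError, match="founder"):
            mendelian_drop({"X": (None, None)}, {}, np.random.default_rng(0))


class TestCohortStructure:
    def test_family_composition_bounds(self, cohort1):
        ped = cohort1.pedigree
        assert len(ped.families) == 21
        for fam in ped.families:
            counts = ped.affection_counts(fam, sequenced_only=True)
            assert 2 <= counts["affected"] <= 4
            assert 0 <= counts["unaffected"] <= 2

    def test_planted_passing_variants_satisfy_every_default_gate(self,
                                                                 cohort1):
        by_key = {r.key: r for r in cohort1.variants}
        for planted in cohort1.ground_truth.planted_variants:
            if not planted.all_passing:
                continue
            rec = by_key[planted.key]
            assert passes_maf(rec.profile)
            assert passes_cadd(rec.profile)
            assert passes_conservation(rec.profile)
            assert predictor_consensus(rec.profile)[1]
            assert evaluate_segregation(rec, cohort1.pedigree).passes

    def test_planted_failing_variants_fail_their_sabotaged_gate(self,
                                                                cohort1):
        by_key = {r.key: r for r in cohort1.variants}
        checks = {
            "maf": lambda r: passes_maf(r.profile),
            "cadd": lambda r: passes_cadd(r.profile),
            "conservation": lambda r: passes_conservation(r.profile),
            "consensus": lambda r: predictor_consensus(r.profile)[1],
            "segregation": lambda r: evaluate_segregation(
                r, cohort1.pedigree).passes,
        }
        n_failing = 0
        for planted in cohort1.ground_truth.planted_variants:
            failing = [g for g, r in planted.regimes.items() if r == "failing"]
            if not failing:
                continue
            n_failing += 1
            (gate,) = failing
            assert not checks[gate](by_key[planted.key]), (planted.key, gate)
        assert n_failing == 21  # one failing-regime plant per family

    def test_background_genotypes_independent_of_affection(self, cohort1):
        """Carrier rates among affected vs unaffected members agree for
        background variants (no planted signal leaks into the null)."""
        planted = {p.key for p in cohort1.ground_truth.planted_variants}
        aff_carr = aff_tot = unaff_carr = unaff_tot = 0
        status = {(m.family_id, m.individual_id): m.affection
                  for m in cohort1.pedigree.individuals}
        for rec in cohort1.variants:
            if rec.key in planted:
                continue
            for iid, gt in rec.genotypes.items():
                carrier = gt in ("het", "hom_alt")
                if status[(rec.family_id, iid)] == "affected":
                    aff_tot += 1
                    aff_carr += carrier
                else:
                    unaff_tot += 1
                    unaff_carr += carrier
        p_aff, p_unaff = aff_carr / aff_tot, unaff_carr / unaff_tot
        se = np.sqrt(0.25 * 0.75 * (1 / aff_tot + 1 / unaff_tot))
        assert abs(p_aff - p_unaff) < 4 * se

    def test_zero_affected_spec_is_rejected(self):
        with pytest.raises(DataError):
            CohortSpec(affected_range=(0, 2))


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = generate_cohort(SMALL)
        b = generate_cohort(SMALL)
        assert a.pedigree == b.pedigree
        assert a.variants == b.variants
        assert a.cnv_segments == b.cnv_segments

    def test_different_seed_different_keys_same_schema(self):
        import dataclasses
        a = generate_cohort(SMALL)
        b = generate_cohort(dataclasses.replace(SMALL, seed=4))
        assert {r.key for r in a.variants} != {r.key for r in b.variants}
        assert len(a.variants) == len(b.variants)
        assert sorted(a.pedigree.families) == sorted(b.pedigree.families)

    def test_written_outputs_byte_identical(self, tmp_path):
        c1 = generate_cohort(SMALL)
        c2 = generate_cohort(SMALL)
        p1 = write_cohort(c1, tmp_path / "a")
        p2 = write_cohort(c2, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name


class TestNullCalibration:
    def test_analytic_probabilities(self):
        assert p_cadd_pass(20.0) == pytest.approx(0.01)
        spec = CohortSpec()
        # log-uniform on [1e-5, 0.05]: P(< 1e-3) = ln(100)/ln(5000)
        assert p_maf_pass(spec) == pytest.approx(
            np.log(100) / np.log(5000))

    def test_background_survivors_match_binomial_prediction(self):
        """With no planted variants, the count of records surviving the
        shared gates matches the analytic gate-pass product within 3
        sigma (the pipeline does not distort the null)."""
        import dataclasses
        from famseq.pipeline import RunConfig, run_cascade
        spec = dataclasses.replace(
            CohortSpec(), planted_passing_per_family=0,
            planted_failing_per_family=0, n_planted_cnvs=0, n_decoy_cnvs=0,
            seed=17)
        cohort = generate_cohort(spec)
        result = run_cascade(cohort.variants, cohort.pedigree, [],
                             cohort.gene_models, RunConfig())
        observed = len(result.shared_survivors)
        mean, sd = null_shared_gate_moments(cohort.pedigree, spec)
        assert abs(observed - mean) <= 3 * sd + 1e-9
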