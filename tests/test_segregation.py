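"""Co-segregation logic: definitional cases, brute-force equivalence over
all genotype assignments, policy monotonicity, CNV carrier logic."""

import itertools

import pytest

from conftest import make_trio
from famseq.model import (
    AnnotationProfile,
    CNVSegment,
    ConsistencyError,
    Individual,
    Pedigree,
    VariantRecord,
)
from famseq.segregation import (
    SegregationPolicy,
    evaluate_cnv_segregation,
    evaluate_segregation,
)


def family(n_affected, n_unaffected, family_id="FAM1"):
    inds = [Individual(f"A{i}", family_id, None, None, "male", "affected")
            for i in range(n_affected)]
    inds += [Individual(f"U{i}", family_id, None, None, "female", "unaffected")
             for i in range(n_unaffected)]
    return Pedigree(inds)


def variant(genotypes, family_id="FAM1"):
    return VariantRecord("chr1", 1000, "A", "G", "missense", "GENE1",
                         family_id, genotypes, AnnotationProfile())


def oracle_passes(members, genotypes, policy):
    """Independent definitional evaluator: explicit carrier-set logic."""
    carriers, excluded = set(), set()
    for m in members:
        gt = genotypes.get(m.individual_id, "missing")
        if gt == "missing":
            if policy.treat_missing_genotype_as == "exclude_individual":
                excluded.add(m.individual_id)
                continue
            if policy.treat_missing_genotype_as == "carrier":
                carriers.add(m.individual_id)
            continue
        if gt in ("het", "hom_alt"):
            carriers.add(m.individual_id)
    aff = [m.individual_id for m in members
           if m.affection == "affected" and m.individual_id not in excluded]
    unaff = [m.individual_id for m in members
             if m.affection == "unaffected" and m.individual_id not in excluded]
    if not aff:
        return False
    return all(a in carriers for a in aff) and \
        sum(u in carriers for u in unaff) <= policy.max_unaffected_carriers


def test_all_affected_het_no_unaffected_carrier_passes():
    ped = family(2, 1)
    res = evaluate_segregation(
        variant({"A0": "het", "A1": "het", "U0": "hom_ref"}), ped)
    assert res.passes
    assert (res.n_affected_carriers, res.n_affected_total) == (2, 2)
    assert (res.n_unaffected_carriers, res.n_unaffected_total) == (0, 1)


def test_unaffected_carrier_fails_unless_allowed():
    ped = family(2, 1)
    v = variant({"A0": "het", "A1": "het", "U0": "het"})
    assert not evaluate_segregation(v, ped).passes
    relaxed = SegregationPolicy(max_unaffected_carriers=1)
    assert evaluate_segregation(v, ped, relaxed).passes


def test_affected_noncarrier_fails():
    ped = family(3, 0)
    v = variant({"A0": "het", "A1": "hom_alt", "A2": "hom_ref"})
    assert not evaluate_segregation(v, ped).passes


@pytest.mark.parametrize("missing_policy, expected", [
    ("exclude_individual", True),   # missing affected dropped from counts
    ("carrier", True),              # imputed carrier keeps the pass
    ("non_carrier", False),         # imputed non-carrier breaks it
])
def test_missing_genotype_policies(missing_policy, expected):
    ped = family(2, 1)
    v = variant({"A0": "het", "A1": "missing", "U0": "hom_ref"})
    policy = SegregationPolicy(treat_missing_genotype_as=missing_policy)
    res = evaluate_segregation(v, ped, policy)
    assert res.passes is expected
    if missing_policy == "exclude_individual":
        assert res.excluded_individuals == ["A1"]
        assert res.n_affected_total == 1


def test_zero_sequenced_affected_is_error():
    ped = Pedigree([
        Individual("U0", "FAM1", None, None, "male", "unaffected"),
        Individual("U1", "FAM1", None, None, "male", "unaffected"),
    ])
    with pytest.raises(ConsistencyError, match="no sequenced affected"):
        evaluate_segregation(variant({"U0": "het", "U1": "het"}), ped)


def test_foreign_sample_is_error():
    ped = make_trio()
    with pytest.raises(ConsistencyError, match="GHOST"):
        evaluate_segregation(variant({"GHOST": "het"}, "FAM1"), ped)


POLICY_GRID = [
    SegregationPolicy(max_unaffected_carriers=m, treat_missing_genotype_as=t)
    for m in (0, 1, 2)
    for t in ("exclude_individual", "carrier", "non_carrier")
]


@pytest.mark.parametrize("n_aff, n_unaff", [(2, 3), (3, 2), (5, 0), (1, 4)])
def test_brute_force_equivalence_all_genotype_assignments(n_aff, n_unaff):
    """For every 3^k genotype assignment on a k<=5-member family and every
    policy in the grid, the evaluator agrees with the definitional oracle
    (missing genotypes included via a 4-state sweep on a smaller family)."""
    ped = family(n_aff, n_unaff)
    members = ped.family_members("FAM1")
    ids = [m.individual_id for m in members]
    for assignment in itertools.product(("hom_ref", "het", "hom_alt"),
                                        repeat=len(ids)):
        genotypes = dict(zip(ids, assignment))
        v = variant(genotypes)
        for policy in POLICY_GRID:
            assert evaluate_segregation(v, ped, policy).passes == \
                oracle_passes(members, genotypes, policy), \
                (genotypes, policy)


def test_brute_force_equivalence_with_missing_states():
    ped = family(2, 1)
    members = ped.family_members("FAM1")
    ids = [m.individual_id for m in members]
    for assignment in itertools.product(
            ("hom_ref", "het", "hom_alt", "missing"), repeat=len(ids)):
        genotypes = dict(zip(ids, assignment))
        v = variant(genotypes)
        for policy in POLICY_GRID:
            assert evaluate_segregation(v, ped, policy).passes == \
                oracle_passes(members, genotypes, policy)


def test_relaxing_unaffected_allowance_is_monotone():
    """A pass never turns into a fail as max_unaffected_carriers grows."""
    ped = family(3, 2)
    ids = [m.individual_id for m in ped.family_members("FAM1")]
    for assignment in itertools.product(("hom_ref", "het"), repeat=len(ids)):
        v = variant(dict(zip(ids, assignment)))
        passes = [evaluate_segregation(
            v, ped, SegregationPolicy(max_unaffected_carriers=m)).passes
            for m in (0, 1, 2)]
        assert passes == sorted(passes)


def test_cnv_segregation_matches_variant_logic():
    ped = family(3, 1)
    seg = CNVSegment("FAM1", "chr4", 15936942, 16178663, "duplication",
                     {"A0": True, "A1": True, "A2": True, "U0": False})
    res = evaluate_cnv_segregation(seg, ped)
    assert res.passes and res.n_affected_carriers == 3

    nobody = CNVSegment("FAM1", "chr4", 100, 200, "deletion",
                        {i: False for i in ("A0", "A1", "A2", "U0")})
    assert not evaluate_cnv_segregation(nobody, ped).passes


def test_cnv_policy_sweep_monotone():
    ped = family(2, 2)
    segs = [CNVSegment("FAM1", "chr1", 1, 100, "duplication",
                       {"A0": True, "A1": True, "U0": u0, "U1": u1})
            for u0 in (False, True) for u1 in (False, True)]
    pass_sets = []
    for m in (0, 1, 2):
        policy = SegregationPolicy(max_unaffected_carriers=m)
        pass_sets.append({i for i, s in enumerate(segs)
                          if evaluate_cnv_segregation(s, ped, policy).passes})
    assert pass_sets[0] <= pass_sets[1] <= pass_sets[2]


def test_result_is_order_independent():
    ped = family(3, 2)
    genotypes = {"A0": "het", "A1": "het", "A2": "het",
                 "U0": "hom_ref", "U1": "het"}
    shuffled = dict(reversed(list(genotypes.items())))
    a = evaluate_segregation(variant(genotypes), ped)
    b = evaluate_segregation(variant(shuffled), ped)
    assert (a.passes, a.n_affected_carriers, a.n_unaffected_carriers) == \
        (b.passes, b.n_affected_carriers, b.n_unaffected_carriers)
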