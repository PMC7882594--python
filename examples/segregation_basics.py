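"""Co-segregation on a small family, and what the unaffected-carrier
allowance changes.

An unaffected carrier fails the strict policy but is tolerated when the
allowance acknowledges that unaffected status in adult-onset disease is
provisional.
"""

from famseq import (
    AnnotationProfile,
    Individual,
    Pedigree,
    SegregationPolicy,
    VariantRecord,
    evaluate_segregation,
)

pedigree = Pedigree([
    Individual("A1", "FAM1", None, None, "male", "affected"),
    Individual("A2", "FAM1", None, None, "female", "affected"),
    Individual("U1", "FAM1", None, None, "female", "unaffected"),
])

variant = VariantRecord("chr9", 124_500_000, "G", "T", "missense", "DAB2IP",
                        "FAM1", {"A1": "het", "A2": "het", "U1": "het"},
                        AnnotationProfile())

for allowance in (0, 1):
    policy = SegregationPolicy(max_unaffected_carriers=allowance)
    res = evaluate_segregation(variant, pedigree, policy)
    print(f"max_unaffected_carriers={allowance}: passes={res.passes} "
          f"(affected carriers {res.n_affected_carriers}/"
          f"{res.n_affected_total}, unaffected carriers "
          f"{res.n_unaffected_carriers}/{res.n_unaffected_total})")
# allowance 0: False — the unaffected het disqualifies the variant;
# allowance 1: True — one presymptomatic carrier is tolerated.
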