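"""Within-family co-segregation of a variant with disease.

A variant co-segregates under the dominant rare-variant model when every
sequenced affected member carries it (het or hom-alt) and the number of
sequenced unaffected carriers does not exceed a configurable allowance
(default 0). Unaffected status in adult-onset cancer families is
provisional — an unaffected carrier today may develop disease later — so
the allowance is a policy knob rather than a fixed rule. Members whose
affection status is unknown are never counted on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

from .model import CNVSegment, ConsistencyError, Pedigree, VariantRecord

CARRIER_GENOTYPES = frozenset({"het", "hom_alt"})
MISSING_POLICIES = ("carrier", "non_carrier", "exclude_individual")


@dataclass(frozen=True)
class SegregationPolicy:
    """How strictly "segregates with disease" is enforced.

    require_all_affected_carriers is the dominant-model core and stays
    on; max_unaffected_carriers relaxes the unaffected-as-control side;
    treat_missing_genotype_as decides what a failed genotype call means.
    """

    require_all_affected_carriers: bool = True
    max_unaffected_carriers: int = 0
    treat_missing_genotype_as: str = "exclude_individual"

    def __post_init__(self) -> None:
        if self.max_unaffected_carriers < 0:
            raise ValueError("max_unaffected_carriers must be >= 0")
        if self.treat_missing_genotype_as not in MISSING_POLICIES:
            raise ValueError(
                f"unknown missing-genotype policy "
                f"{self.treat_missing_genotype_as!r}"
            )


@dataclass
class SegregationResult:
    family_id: str
    passes: bool
    n_affected_carriers: int
    n_affected_total: int
    n_unaffected_carriers: int
    n_unaffected_total: int
    excluded_individuals: List[str] = field(default_factory=list)


def _evaluate(family_id: str, carrier_of: Dict[str, object],
              pedigree: Pedigree, policy: SegregationPolicy
              ) -> SegregationResult:
    """Shared pass logic; carrier_of maps individual -> True/False/None
    (None = missing observation)."""
    members = pedigree.sequenced_members(family_id)
    if not any(m.affection == "affected" for m in members):
        raise ConsistencyError(
            f"family {family_id!r} has no sequenced affected members; "
            "segregation is uninterpretable"
        )
    excluded: List[str] = []
    n_aff = n_aff_carr = n_unaff = n_unaff_carr = 0
    for m in members:
        if m.affection == "unknown":
            continue
        carrier = carrier_of.get(m.individual_id)
        if carrier is None:
            if policy.treat_missing_genotype_as == "exclude_individual":
                excluded.append(m.individual_id)
                continue
            carrier = policy.treat_missing_genotype_as == "carrier"
        if m.affection == "affected":
            n_aff += 1
            n_aff_carr += carrier
        else:
            n_unaff += 1
            n_unaff_carr += carrier
    affected_ok = (n_aff_carr == n_aff and n_aff >= 1) \
        if policy.require_all_affected_carriers else n_aff_carr >= 1
    passes = affected_ok and n_unaff_carr <= policy.max_unaffected_carriers
    return SegregationResult(
        family_id=family_id, passes=passes,
        n_affected_carriers=n_aff_carr, n_affected_total=n_aff,
        n_unaffected_carriers=n_unaff_carr, n_unaffected_total=n_unaff,
        excluded_individuals=excluded,
    )


def evaluate_segregation(variant: VariantRecord, pedigree: Pedigree,
                         policy: SegregationPolicy = SegregationPolicy()
                         ) -> SegregationResult:
    """Decide whether one variant co-segregates with disease in its family.

    Genotype keys must refer to sequenced members of the variant's
    family; a member without a genotype entry is treated as a missing
    call. Raises :class:`ConsistencyError` when the family has no
    sequenced affected members.
    """
    members = {m.individual_id for m in
               pedigree.sequenced_members(variant.family_id)}
    stray = set(variant.genotypes) - members
    if stray:
        raise ConsistencyError(
            f"genotypes for non-sequenced or foreign individuals "
            f"{sorted(stray)} on variant {variant.key} "
            f"(family {variant.family_id!r})"
        )
    carrier_of = {}
    for iid, gt in variant.genotypes.items():
        carrier_of[iid] = None if gt == "missing" else gt in CARRIER_GENOTYPES
    return _evaluate(variant.family_id, carrier_of, pedigree, policy)


def evaluate_cnv_segregation(segment: CNVSegment, pedigree: Pedigree,
                             policy: SegregationPolicy = SegregationPolicy()
                             ) -> SegregationResult:
    """Same pass logic for a CNV segment; carrier = flagged True.

    A member absent from the carrier map counts as a missing observation
    and follows the policy's missing-genotype rule.
    """
    members = {m.individual_id for m in
               pedigree.sequenced_members(segment.family_id)}
    stray = set(segment.carriers) - members
    if stray:
        raise ConsistencyError(
            f"carrier flags for non-sequenced or foreign individuals "
            f"{sorted(stray)} on CNV {segment.key}"
        )
    carrier_of: Dict[str, object] = dict(segment.carriers)
    return _evaluate(segment.family_id, carrier_of, pedigree, policy)
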