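"""Missense prioritization: conservation gates, predictor consensus, and
gene-intolerance screening.

Variants reaching this track already passed the shared gates (rarity,
segregation, CADD). Three further evidence layers apply:

* Evolutionary conservation at the site — GERP > 2.0, PhastCons > 0.3,
  PhyloP >= 3.0 (boundary operators as conventionally printed for these
  scores). Every score that is present must pass, and at least one must
  be present; requiring all three to exist would penalise exome-only
  annotation coverage.
* A consensus over ten in-silico deleteriousness predictors (SIFT, the
  two PolyPhen-2 models, LRT, MutationTaster, MutationAssessor, FATHMM,
  MetaSVM, MetaLR, PROVEAN): a strict majority of the non-missing calls
  must be "deleterious", with at least five calls available. Records
  with fewer calls are routed to a needs-review stratum rather than
  silently dropped.
* Gene-level intolerance to functional variation (ExAC missense Z-score
  and rank percentiles in three reference sets). By default this is
  attached as evidence, not filtered on: well-established predisposition
  genes are not uniformly intolerant, so a hard cut is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import AnnotationProfile, DataError, VariantRecord, variant_sort_key


@dataclass(frozen=True)
class ConservationGate:
    gerp_min: float = 2.0        # strict >
    phastcons_min: float = 0.3   # strict >
    phylop_min: float = 3.0      # inclusive >=


@dataclass(frozen=True)
class ConsensusRule:
    min_deleterious_fraction: float = 0.5  # strict majority of non-missing calls
    min_calls_available: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_deleterious_fraction <= 1:
            raise ValueError("min_deleterious_fraction must be in (0, 1]")


@dataclass(frozen=True)
class IntoleranceCutoffs:
    z_cutoff: float = 0.0           # intolerant if exac_z > cutoff
    percentile_cutoff: float = 25.0  # intolerant if any percentile <= cutoff
                                     # (low percentile = most intolerant)


@dataclass
class IntoleranceSummary:
    gene_symbol: str
    exac_z: Optional[float]
    percentiles: Dict[str, float]
    intolerant_flag: bool


@dataclass
class MissenseEvidence:
    """All gate outcomes for one record, fully populated."""

    conservation_pass: bool
    consensus_fraction: float
    consensus_available: int
    consensus_pass: bool
    intolerance: IntoleranceSummary
    needs_review: bool  # conservation evidence present but too few calls

    @property
    def hard_pass(self) -> bool:
        return self.conservation_pass and self.consensus_pass


@dataclass
class MissenseCandidate:
    record: VariantRecord
    evidence: MissenseEvidence


def passes_conservation(profile: AnnotationProfile,
                        gate: ConservationGate = ConservationGate()) -> bool:
    """True iff every present conservation score passes its threshold and
    at least one score is present; all-missing is no evidence => False."""
    checks: List[bool] = []
    if profile.gerp is not None:
        checks.append(profile.gerp > gate.gerp_min)
    if profile.phastcons is not None:
        checks.append(profile.phastcons > gate.phastcons_min)
    if profile.phylop is not None:
        checks.append(profile.phylop >= gate.phylop_min)
    return bool(checks) and all(checks)


def predictor_consensus(profile: AnnotationProfile,
                        rule: ConsensusRule = ConsensusRule()
                        ) -> Tuple[float, bool]:
    """Fraction of non-missing predictor calls that are deleterious, and
    whether the consensus gate passes (fraction strictly above the rule's
    threshold with enough calls available). With zero calls the fraction
    is reported as 0.0."""
    n_del = sum(1 for c in profile.predictor_calls.values()
                if c == "deleterious")
    n_avail = len(profile.predictor_calls)
    fraction = n_del / n_avail if n_avail else 0.0
    passes = (n_avail >= rule.min_calls_available
              and fraction > rule.min_deleterious_fraction)
    return fraction, passes


def assess_intolerance(gene_symbol: str, profile: AnnotationProfile,
                       cutoffs: IntoleranceCutoffs = IntoleranceCutoffs()
                       ) -> IntoleranceSummary:
    """Summarise gene-level intolerance evidence; always emitted, even
    when every field is missing (flag False)."""
    z = profile.exac_z
    pct = dict(profile.intolerance_percentiles)
    flag = (z is not None and z > cutoffs.z_cutoff) or any(
        p <= cutoffs.percentile_cutoff for p in pct.values())
    return IntoleranceSummary(gene_symbol=gene_symbol, exac_z=z,
                              percentiles=pct, intolerant_flag=flag)


def prioritize_missense(records: Sequence[VariantRecord],
                        gate: ConservationGate = ConservationGate(),
                        rule: ConsensusRule = ConsensusRule(),
                        cutoffs: IntoleranceCutoffs = IntoleranceCutoffs(),
                        mode: str = "hard_filter",
                        intolerance_filter: bool = False
                        ) -> List[MissenseCandidate]:
    """Apply the missense evidence layers to pre-gated records.

    ``hard_filter`` returns only records passing conservation AND
    consensus (AND intolerance when ``intolerance_filter``); ``annotate``
    returns every record with its evidence attached. Output order is
    stable: (chrom, pos, alt).
    """
    if mode not in ("annotate", "hard_filter"):
        raise ValueError(f"unknown mode {mode!r}")
    out: List[MissenseCandidate] = []
    for rec in records:
        if rec.consequence != "missense":
            raise DataError(
                f"non-missense record {rec.key} ({rec.consequence}) "
                "in missense track"
            )
        cons = passes_conservation(rec.profile, gate)
        fraction, cons_pass = predictor_consensus(rec.profile, rule)
        intl = assess_intolerance(rec.gene_symbol, rec.profile, cutoffs)
        has_conservation_evidence = any(
            s is not None for s in (rec.profile.gerp, rec.profile.phastcons,
                                    rec.profile.phylop))
        ev = MissenseEvidence(
            conservation_pass=cons,
            consensus_fraction=fraction,
            consensus_available=len(rec.profile.predictor_calls),
            consensus_pass=cons_pass,
            intolerance=intl,
            needs_review=(has_conservation_evidence
                          and len(rec.profile.predictor_calls)
                          < rule.min_calls_available),
        )
        keep = ev.hard_pass and (intl.intolerant_flag or not intolerance_filter)
        if mode == "annotate" or keep:
            out.append(MissenseCandidate(record=rec, evidence=ev))
    out.sort(key=lambda c: variant_sort_key(c.record))
    return out
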