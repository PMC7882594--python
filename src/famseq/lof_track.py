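"""Loss-of-function triage.

Frameshift and stopgain variants are gated on the precomputed
MutPred-LOF pathogenicity score (strictly above 0.50, the threshold
calibrated to a 5% false-positive rate by that tool's authors); splice
site variants are gated on the splicing-motif yes/no flag produced by a
splice-effect predictor such as Human Splicing Finder. Both the full LoF
list and the thresholded sublist are reported, since the score gate is a
triage aid rather than a hard exclusion. A record whose score or flag is
missing lands in a needs-review stratum by default.

The LoF vocabulary here is deliberately narrow — frameshift, stopgain,
splice site — matching how these variant classes are triaged in
family-based prioritization; start-loss/stop-loss are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

from .model import DataError, VariantRecord, variant_sort_key

LOF_CLASSES = ("frameshift", "stopgain", "splice_site")
SCORED_LOF_CLASSES = ("frameshift", "stopgain")


@dataclass(frozen=True)
class LofGate:
    mutpred_threshold: float = 0.50      # strict >
    missing_score_policy: str = "needs_review"  # or "fail"

    def __post_init__(self) -> None:
        if not 0 < self.mutpred_threshold < 1:
            raise ValueError("mutpred_threshold must be in (0, 1)")
        if self.missing_score_policy not in ("needs_review", "fail"):
            raise ValueError(
                f"unknown missing-score policy {self.missing_score_policy!r}"
            )


def classify_lof(record: VariantRecord) -> str:
    """Map a record's consequence to its LoF class, or ``not_lof``."""
    return record.consequence if record.consequence in LOF_CLASSES else "not_lof"


def passes_mutpred(record: VariantRecord, gate: LofGate = LofGate()) -> str:
    """Gate a frameshift/stopgain record on MutPred-LOF: ``pass`` iff the
    score is strictly above the threshold; missing per policy."""
    if classify_lof(record) not in SCORED_LOF_CLASSES:
        raise DataError(
            f"passes_mutpred called on {record.consequence!r} record "
            f"{record.key}"
        )
    score = record.profile.mutpred_lof
    if score is None:
        return gate.missing_score_policy if \
            gate.missing_score_policy == "needs_review" else "fail"
    return "pass" if score > gate.mutpred_threshold else "fail"


def passes_splice(record: VariantRecord, gate: LofGate = LofGate()) -> str:
    """Gate a splice-site record on the splicing-motif flag: yes => pass,
    no => fail, missing => needs_review (or fail per policy)."""
    if classify_lof(record) != "splice_site":
        raise DataError(
            f"passes_splice called on {record.consequence!r} record "
            f"{record.key}"
        )
    flag = record.profile.hsf_alters_splicing
    if flag is None:
        return gate.missing_score_policy if \
            gate.missing_score_policy == "needs_review" else "fail"
    return "pass" if flag == "yes" else "fail"


@dataclass
class LofCandidate:
    record: VariantRecord
    lof_class: str
    gate_status: str  # pass | fail | needs_review


def triage_lof(records: Sequence[VariantRecord],
               gate: LofGate = LofGate()) -> List[LofCandidate]:
    """Gate every LoF record by its class-appropriate rule.

    Returns the full annotated list in stable (chrom, pos, alt) order;
    the thresholded sublist is the subset with ``gate_status == "pass"``.
    Non-LoF records are a caller error.
    """
    out: List[LofCandidate] = []
    for rec in records:
        cls = classify_lof(rec)
        if cls == "not_lof":
            raise DataError(f"non-LoF record {rec.key} in LoF track")
        status = (passes_splice(rec, gate) if cls == "splice_site"
                  else passes_mutpred(rec, gate))
        out.append(LofCandidate(record=rec, lof_class=cls, gate_status=status))
    out.sort(key=lambda c: variant_sort_key(c.record))
    return out


def class_counts(candidates: Sequence[LofCandidate]) -> Dict[str, int]:
    counts = {cls: 0 for cls in LOF_CLASSES}
    for c in candidates:
        counts[c.lof_class] += 1
    return counts
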