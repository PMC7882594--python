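"""Cohort-level reporting: per-family gradual-filtering traces,
cross-family gene recurrence, and the family-privacy check.

The gradual-filtering trace records, per family, how many variants
survive each cascade stage in order (input, rarity, segregation, CADD,
then the track gates); counts must be nonincreasing because each stage
only removes variants. The recurrence report finds genes hit in two or
more distinct families — the interesting pattern is *different* variants
in the same gene across unrelated families, while the *same* variant key
appearing in several families ("private violation") more often flags a
pipeline or annotation artifact than shared inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .model import ConsistencyError, VariantKey


@dataclass
class FilterTrace:
    family_id: str
    stages: List[str]
    counts: List[int]

    def as_dict(self) -> Dict[str, int]:
        return dict(zip(self.stages, self.counts))


class StageLog:
    """Accumulates, per stage and family, the set of surviving variant keys.

    Stages must be recorded in cascade order; each family's survivor set
    at a stage must be a subset of its set at the previous stage.
    """

    def __init__(self) -> None:
        self.stages: List[str] = []
        self.survivors: List[Dict[str, Set[VariantKey]]] = []

    def record(self, stage: str,
               survivors_by_family: Dict[str, Set[VariantKey]]) -> None:
        self.stages.append(stage)
        self.survivors.append(
            {fam: set(keys) for fam, keys in survivors_by_family.items()})


def build_trace(log: StageLog) -> List[FilterTrace]:
    """Turn a stage log into per-family count traces.

    Raises :class:`ConsistencyError` if any stage's survivors are not a
    subset of the previous stage's (an impossible filter outcome that
    indicates a bookkeeping bug upstream).
    """
    families = sorted({fam for stage in log.survivors for fam in stage})
    for i in range(1, len(log.stages)):
        prev, cur = log.survivors[i - 1], log.survivors[i]
        for fam in families:
            extra = cur.get(fam, set()) - prev.get(fam, set())
            if extra:
                raise ConsistencyError(
                    f"stage {log.stages[i]!r} has survivors absent from "
                    f"stage {log.stages[i-1]!r} for family {fam!r}: "
                    f"{sorted(extra)[:3]}"
                )
    traces = []
    for fam in families:
        counts = [len(stage.get(fam, set())) for stage in log.survivors]
        traces.append(FilterTrace(family_id=fam, stages=list(log.stages),
                                  counts=counts))
    return traces


def cohort_counts(traces: Sequence[FilterTrace]) -> Dict[str, int]:
    """Cohort-wide count per stage = sum of the per-family counts."""
    totals: Dict[str, int] = {}
    for t in traces:
        for stage, n in zip(t.stages, t.counts):
            totals[stage] = totals.get(stage, 0) + n
    return totals


@dataclass
class RecurrenceReport:
    by_gene: Dict[str, List[Tuple[str, VariantKey]]]
    recurrent_genes: List[str] = field(default_factory=list)
    private_violations: List[Tuple[VariantKey, List[str]]] = \
        field(default_factory=list)


def find_recurrent_genes(
        candidates: Iterable[Tuple[str, str, VariantKey]]) -> RecurrenceReport:
    """Cross-family recurrence from (family_id, gene_symbol, variant_key)
    candidate tuples.

    ``recurrent_genes`` lists genes hit in >= 2 distinct families;
    ``private_violations`` lists identical variant keys observed in more
    than one family.
    """
    by_gene: Dict[str, List[Tuple[str, VariantKey]]] = {}
    fams_by_key: Dict[VariantKey, Set[str]] = {}
    for family_id, gene, key in candidates:
        by_gene.setdefault(gene, []).append((family_id, key))
        fams_by_key.setdefault(key, set()).add(family_id)
    recurrent = sorted(
        g for g, hits in by_gene.items()
        if len({fam for fam, _ in hits}) >= 2)
    violations = sorted(
        (key, sorted(fams)) for key, fams in fams_by_key.items()
        if len(fams) >= 2)
    return RecurrenceReport(by_gene=by_gene, recurrent_genes=recurrent,
                            private_violations=violations)


def intersect_gene_list(candidate_genes: Iterable[str],
                        reference_genes: Iterable[str]) -> List[str]:
    """Utility intersection against a user-supplied gene list (e.g. a
    somatic-driver catalogue), sorted alphabetically."""
    ref = set(reference_genes)
    return sorted(set(candidate_genes) & ref)
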