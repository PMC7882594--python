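"""CNV prioritization: family segregation plus coding-gene overlap.

A CNV candidate is a segment whose carrier pattern co-segregates with
disease in its family, annotated with every gene whose coding region it
overlaps by at least one base. Copy-number dosage is not modelled —
carrier status is binary — and no population-frequency gate applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

from .model import CNVSegment, GeneModelSet, chrom_sort_key
from .segregation import SegregationPolicy, SegregationResult, \
    evaluate_cnv_segregation
from .model import Pedigree


@dataclass
class CnvCandidate:
    segment: CNVSegment
    segregation: SegregationResult
    genes_overlapped: List[str]


def genes_overlapping(segment: CNVSegment, genes: GeneModelSet,
                      min_overlap_fraction: float = 0.0) -> List[str]:
    """Gene symbols whose coding region the segment overlaps.

    Default criterion is >= 1 base of overlap; ``min_overlap_fraction``
    (of the gene's effective span) is available for sensitivity
    analyses. Result is duplicate-free and sorted by (chrom, start,
    symbol), hence deterministic for a fixed gene-model set.
    """
    hits = genes.overlapping_genes(segment.chrom, segment.start, segment.end)
    if min_overlap_fraction <= 0:
        return hits
    kept = []
    span_of = {}
    for f in genes.features:
        if f.gene_symbol in hits and f.chrom == segment.chrom:
            span_of.setdefault(f.gene_symbol, []).append(f)
    for gene in hits:
        feats = span_of[gene]
        coding = [f for f in feats if f.feature == "coding_region"]
        feats = coding or feats
        total = sum(f.end - f.start + 1 for f in feats)
        overlap = sum(max(0, min(f.end, segment.end)
                          - max(f.start, segment.start) + 1) for f in feats)
        if total and overlap / total >= min_overlap_fraction:
            kept.append(gene)
    return kept


def prioritize_cnvs(segments: Sequence[CNVSegment], pedigree: Pedigree,
                    genes: GeneModelSet,
                    policy: SegregationPolicy = SegregationPolicy(),
                    min_overlap_fraction: float = 0.0) -> List[CnvCandidate]:
    """Return segregating CNVs with their overlapped coding genes.

    Output order is (family, chrom, start, end, type), independent of
    input order.
    """
    out: List[CnvCandidate] = []
    for seg in segments:
        result = evaluate_cnv_segregation(seg, pedigree, policy)
        if result.passes:
            out.append(CnvCandidate(
                segment=seg, segregation=result,
                genes_overlapped=genes_overlapping(
                    seg, genes, min_overlap_fraction),
            ))
    out.sort(key=lambda c: (c.segment.family_id,
                            chrom_sort_key(c.segment.chrom),
                            c.segment.start, c.segment.end,
                            c.segment.cnv_type))
    return out


def distinct_genes(candidates: Sequence[CnvCandidate]) -> List[str]:
    """All distinct genes across candidates, in first-seen candidate order
    then symbol order."""
    seen = []
    for c in candidates:
        for g in c.genes_overlapped:
            if g not in seen:
                seen.append(g)
    return seen
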