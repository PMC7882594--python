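"""CNV prioritization: the chr4 worked example, per-base oracle
equivalence of the interval engine, and cohort-level candidate recovery."""

import numpy as np
import pytest

from famseq.cnv_track import distinct_genes, genes_overlapping, prioritize_cnvs
from famseq.model import CNVSegment, GeneFeature, GeneModelSet
from famseq.segregation import SegregationPolicy
from famseq.synthetic_cohort import cnv_worked_example


def test_chr4_worked_example():
    """The chr4:15936942-16178663 duplication overlaps exactly the four
    fixture genes placed inside it."""
    segment, genes = cnv_worked_example()
    assert genes_overlapping(segment, genes) == \
        ["FGFBP1", "FGFBP2", "PROM1", "TAPT1"]


def test_no_overlap_is_empty():
    genes = GeneModelSet([GeneFeature("G1", "chr1", 1000, 2000)])
    seg = CNVSegment("F1", "chr1", 5000, 6000, "deletion", {})
    assert genes_overlapping(seg, genes) == []
    seg2 = CNVSegment("F1", "chr2", 1000, 2000, "deletion", {})
    assert genes_overlapping(seg2, genes) == []


def test_single_base_overlap_boundary():
    """One base of coding overlap includes the gene; ending one base
    short excludes it."""
    genes = GeneModelSet([
        GeneFeature("G1", "chr1", 900, 2100, "+", "gene"),
        GeneFeature("G1", "chr1", 1000, 2000, "+", "coding_region"),
    ])
    touching = CNVSegment("F1", "chr1", 2000, 3000, "duplication", {})
    short = CNVSegment("F1", "chr1", 2001, 3000, "duplication", {})
    assert genes_overlapping(touching, genes) == ["G1"]
    assert genes_overlapping(short, genes) == []   # gene span is not queried
    at_start = CNVSegment("F1", "chr1", 500, 1000, "duplication", {})
    before = CNVSegment("F1", "chr1", 500, 999, "duplication", {})
    assert genes_overlapping(at_start, genes) == ["G1"]
    assert genes_overlapping(before, genes) == []


def brute_force_overlap(segment, features):
    """Per-base oracle on a toy genome: a gene overlaps iff any coding
    base falls inside the segment."""
    hits = {}
    coding_genes = {f.gene_symbol for f in features
                    if f.feature == "coding_region"}
    for f in features:
        if f.chrom != segment.chrom:
            continue
        if f.gene_symbol in coding_genes and f.feature != "coding_region":
            continue
        for base in range(f.start, f.end + 1):
            if segment.start <= base <= segment.end:
                hits.setdefault(f.gene_symbol, f.start)
                break
    return sorted(hits, key=lambda g: (hits[g], g))


def test_interval_engine_matches_per_base_oracle():
    """Seeded random gene models and segments on a <=100 kb toy genome:
    the interval engine agrees with exhaustive per-base scanning."""
    rng = np.random.default_rng(11)
    for trial in range(20):
        features = []
        for g in range(rng.integers(3, 12)):
            start = int(rng.integers(1, 90_000))
            end = start + int(rng.integers(0, 9_000))
            features.append(GeneFeature(f"G{g}", "chrT", start, end, "+",
                                        "coding_region" if rng.random() < 0.7
                                        else "gene"))
        genes = GeneModelSet(features)
        for s in range(10):
            start = int(rng.integers(1, 95_000))
            seg = CNVSegment("F1", "chrT", start,
                             start + int(rng.integers(0, 20_000)),
                             "duplication", {})
            assert genes_overlapping(seg, genes) == \
                brute_force_overlap(seg, features), (trial, s)


def test_gene_model_record_order_irrelevant():
    rng = np.random.default_rng(3)
    features = [GeneFeature(f"G{i}", "chr1", 1000 * i + 1, 1000 * i + 500)
                for i in range(20)]
    seg = CNVSegment("F1", "chr1", 1, 8000, "deletion", {})
    baseline = genes_overlapping(seg, GeneModelSet(features))
    for _ in range(5):
        perm = [features[i] for i in rng.permutation(len(features))]
        assert genes_overlapping(seg, GeneModelSet(perm)) == baseline


def test_min_overlap_fraction_filters():
    genes = GeneModelSet([GeneFeature("G1", "chr1", 1000, 2000, "+",
                                      "coding_region")])
    sliver = CNVSegment("F1", "chr1", 1990, 5000, "duplication", {})
    assert genes_overlapping(sliver, genes) == ["G1"]
    assert genes_overlapping(sliver, genes, min_overlap_fraction=0.5) == []
    half = CNVSegment("F1", "chr1", 1500, 5000, "duplication", {})
    assert genes_overlapping(half, genes, min_overlap_fraction=0.5) == ["G1"]


def test_cohort_cnv_recovery(cohort1):
    """Exactly the seven planted segregating CNVs are returned, jointly
    overlapping eleven distinct coding genes; decoys all fail."""
    out = prioritize_cnvs(cohort1.cnv_segments, cohort1.pedigree,
                          cohort1.gene_models)
    assert len(out) == 7
    assert {c.segment.key for c in out} == \
        set(cohort1.ground_truth.planted_cnv_keys)
    assert len(distinct_genes(out)) == 11


def test_all_decoys_empty_output(cohort1):
    planted = set(cohort1.ground_truth.planted_cnv_keys)
    decoys = [s for s in cohort1.cnv_segments if s.key not in planted]
    assert prioritize_cnvs(decoys, cohort1.pedigree,
                           cohort1.gene_models) == []


def test_input_order_invariance(cohort1):
    rng = np.random.default_rng(5)
    shuffled = [cohort1.cnv_segments[i]
                for i in rng.permutation(len(cohort1.cnv_segments))]
    a = prioritize_cnvs(cohort1.cnv_segments, cohort1.pedigree,
                        cohort1.gene_models)
    b = prioritize_cnvs(shuffled, cohort1.pedigree, cohort1.gene_models)
    assert [c.segment.key for c in a] == [c.segment.key for c in b]
    assert [c.genes_overlapped for c in a] == [c.genes_overlapped for c in b]
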