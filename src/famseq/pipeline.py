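"""End-to-end cascade: shared gates, per-track prioritization, reporting.

Stage order is rarity -> segregation -> CADD, then the consequence-
specific tracks (missense evidence layers; LoF score/flag gates; CNV
segregation + gene overlap). Rarity and segregation act jointly in
spirit — both are family-level credibility gates — but are logged as
separate stages so per-family attrition is diagnosable.

All outputs are deterministic TSV/JSON with fixed column order and fixed
float precision, so identical (inputs, config) re-runs are byte
identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import yaml

from .aggregate_report import (
    FilterTrace,
    RecurrenceReport,
    StageLog,
    build_trace,
    find_recurrent_genes,
)
from .cnv_track import CnvCandidate, distinct_genes, prioritize_cnvs
from .core_filters import FilterConfig, passes_cadd, passes_maf
from .lof_track import LofCandidate, LofGate, triage_lof
from .missense_track import (
    ConsensusRule,
    ConservationGate,
    IntoleranceCutoffs,
    MissenseCandidate,
    prioritize_missense,
)
from .model import (
    CNVSegment,
    ConsistencyError,
    GeneModelSet,
    Pedigree,
    VariantKey,
    VariantRecord,
    variant_sort_key,
)
from .segregation import SegregationPolicy, evaluate_segregation

SHARED_STAGES = ("input", "maf", "segregation", "cadd")


@dataclass
class RunConfig:
    """Every knob of one cascade run, with defaults matching the
    published thresholds."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    segregation: SegregationPolicy = field(default_factory=SegregationPolicy)
    conservation: ConservationGate = field(default_factory=ConservationGate)
    consensus: ConsensusRule = field(default_factory=ConsensusRule)
    intolerance: IntoleranceCutoffs = field(default_factory=IntoleranceCutoffs)
    lof: LofGate = field(default_factory=LofGate)
    missense_mode: str = "hard_filter"      # or "annotate"
    intolerance_filter: bool = False
    min_cnv_overlap_fraction: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "filters": FilterConfig, "segregation": SegregationPolicy,
            "conservation": ConservationGate, "consensus": ConsensusRule,
            "intolerance": IntoleranceCutoffs, "lof": LofGate,
        }
        scalars = {"missense_mode", "intolerance_filter",
                   "min_cnv_overlap_fraction"}
        unknown = set(data) - set(sections) - scalars
        if unknown:
            raise ConsistencyError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, typ in sections.items():
            if key in data:
                section = data[key]
                legal = {f.name for f in dataclasses.fields(typ)}
                bad = set(section) - legal
                if bad:
                    raise ConsistencyError(
                        f"unknown config keys in {key!r}: {sorted(bad)}"
                    )
                kwargs[key] = typ(**{k: (tuple(v) if isinstance(v, list) else v)
                                     for k, v in section.items()})
        for key in scalars:
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class PipelineResult:
    config: RunConfig
    traces: List[FilterTrace]
    missense: List[MissenseCandidate]
    lof: List[LofCandidate]
    cnv: List[CnvCandidate]
    recurrence: RecurrenceReport
    shared_survivors: List[VariantRecord]

    @property
    def lof_thresholded(self) -> List[LofCandidate]:
        return [c for c in self.lof if c.gate_status == "pass"]

    def candidate_gene_symbols(self) -> List[str]:
        """Distinct gene symbols across all three tracks."""
        genes: Set[str] = {c.record.gene_symbol for c in self.missense}
        genes |= {c.record.gene_symbol for c in self.lof}
        genes |= set(distinct_genes(self.cnv))
        return sorted(genes)


def _audit_thresholds(cfg: RunConfig, summary: dict) -> None:
    """Internal audit: the summary's echoed thresholds must equal the
    config actually applied."""
    if summary["config"] != cfg.to_dict():
        raise ConsistencyError("run summary thresholds diverge from the "
                               "applied configuration")  # pragma: no cover


def validate_inputs(variants: Sequence[VariantRecord],
                    pedigree: Pedigree) -> None:
    """Fail fast on variant/pedigree inconsistencies."""
    known_fams = set(pedigree.families)
    for rec in variants:
        if rec.family_id not in known_fams:
            raise ConsistencyError(
                f"variant {rec.key} references unknown family "
                f"{rec.family_id!r}"
            )
        members = {m.individual_id
                   for m in pedigree.sequenced_members(rec.family_id)}
        stray = set(rec.genotypes) - members
        if stray:
            raise ConsistencyError(
                f"variant {rec.key}: genotyped samples {sorted(stray)} are "
                f"not sequenced members of family {rec.family_id!r}"
            )


def run_cascade(variants: Sequence[VariantRecord], pedigree: Pedigree,
                cnv_segments: Sequence[CNVSegment] = (),
                gene_models: Optional[GeneModelSet] = None,
                config: RunConfig = RunConfig()) -> PipelineResult:
    """Run the full prioritization cascade in memory."""
    validate_inputs(variants, pedigree)
    log = StageLog()

    def by_family(records: Sequence[VariantRecord]
                  ) -> Dict[str, Set[VariantKey]]:
        out: Dict[str, Set[VariantKey]] = {fam: set()
                                           for fam in pedigree.families}
        for rec in records:
            out[rec.family_id].add(rec.key)
        return out

    ordered = sorted(variants, key=lambda r: (r.family_id,
                                              variant_sort_key(r)))
    log.record("input", by_family(ordered))

    after_maf = [r for r in ordered if passes_maf(r.profile, config.filters)]
    log.record("maf", by_family(after_maf))

    after_seg = [r for r in after_maf
                 if evaluate_segregation(r, pedigree,
                                         config.segregation).passes]
    log.record("segregation", by_family(after_seg))

    after_cadd = [r for r in after_seg
                  if passes_cadd(r.profile, config.filters)]
    log.record("cadd", by_family(after_cadd))

    missense_in = [r for r in after_cadd if r.consequence == "missense"]
    lof_in = [r for r in after_cadd
              if r.consequence in ("frameshift", "stopgain", "splice_site")]

    missense = prioritize_missense(
        missense_in, gate=config.conservation, rule=config.consensus,
        cutoffs=config.intolerance, mode=config.missense_mode,
        intolerance_filter=config.intolerance_filter)
    log.record("missense_track",
               by_family([c.record for c in missense
                          if c.evidence.hard_pass]))

    lof = triage_lof(lof_in, gate=config.lof)
    cnv = prioritize_cnvs(cnv_segments, pedigree,
                          gene_models or GeneModelSet([]),
                          policy=config.segregation,
                          min_overlap_fraction=config.min_cnv_overlap_fraction)

    candidates: List[Tuple[str, str, VariantKey]] = []
    for c in missense:
        if c.evidence.hard_pass:
            candidates.append((c.record.family_id, c.record.gene_symbol,
                               c.record.key))
    for c in lof:
        candidates.append((c.record.family_id, c.record.gene_symbol,
                           c.record.key))
    recurrence = find_recurrent_genes(candidates)

    return PipelineResult(config=config, traces=build_trace(log),
                          missense=missense, lof=lof, cnv=cnv,
                          recurrence=recurrence,
                          shared_survivors=after_cadd)


# ---------------------------------------------------------------------------
# deterministic writers

def _f(x: Optional[float]) -> str:
    return "" if x is None else f"{float(x):.6f}"


def write_trace_tsv(traces: Sequence[FilterTrace],
                    path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        if not traces:
            fh.write("family\n")
            return
        stages = traces[0].stages
        fh.write("\t".join(["family"] + list(stages)) + "\n")
        for t in sorted(traces, key=lambda t: t.family_id):
            fh.write("\t".join([t.family_id] + [str(c) for c in t.counts])
                     + "\n")


def write_missense_tsv(candidates: Sequence[MissenseCandidate],
                       path: Union[str, Path]) -> None:
    cols = ["family", "chrom", "pos", "ref", "alt", "gene",
            "conservation_pass", "consensus_fraction", "consensus_available",
            "consensus_pass", "intolerant_flag", "needs_review", "hard_pass"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            r, e = c.record, c.evidence
            fh.write("\t".join([
                r.family_id, r.chrom, str(r.pos), r.ref, r.alt, r.gene_symbol,
                str(int(e.conservation_pass)), _f(e.consensus_fraction),
                str(e.consensus_available), str(int(e.consensus_pass)),
                str(int(e.intolerance.intolerant_flag)),
                str(int(e.needs_review)), str(int(e.hard_pass)),
            ]) + "\n")


def write_lof_tsv(candidates: Sequence[LofCandidate],
                  path: Union[str, Path]) -> None:
    cols = ["family", "chrom", "pos", "ref", "alt", "gene", "lof_class",
            "mutpred_lof", "hsf_alters_splicing", "gate_status"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            r = c.record
            fh.write("\t".join([
                r.family_id, r.chrom, str(r.pos), r.ref, r.alt, r.gene_symbol,
                c.lof_class, _f(r.profile.mutpred_lof),
                r.profile.hsf_alters_splicing or "", c.gate_status,
            ]) + "\n")


def write_cnv_tsv(candidates: Sequence[CnvCandidate],
                  path: Union[str, Path]) -> None:
    cols = ["family", "chrom", "start", "end", "type", "gene",
            "n_affected_carriers", "n_unaffected_carriers"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            s = c.segment
            for gene in (c.genes_overlapped or ["."]):
                fh.write("\t".join([
                    s.family_id, s.chrom, str(s.start), str(s.end),
                    s.cnv_type, gene,
                    str(c.segregation.n_affected_carriers),
                    str(c.segregation.n_unaffected_carriers),
                ]) + "\n")


def write_recurrence_tsv(report: RecurrenceReport,
                         path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tn_families\tfamilies\trecurrent\n")
        for gene in sorted(report.by_gene):
            fams = sorted({fam for fam, _ in report.by_gene[gene]})
            fh.write("\t".join([
                gene, str(len(fams)), ",".join(fams),
                str(int(gene in report.recurrent_genes)),
            ]) + "\n")


def write_outputs(result: PipelineResult, outdir: Union[str, Path]) -> dict:
    """Write every report file plus a machine-readable run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trace_tsv(result.traces, outdir / "trace.tsv")
    write_missense_tsv(result.missense, outdir / "candidates_missense.tsv")
    write_lof_tsv(result.lof, outdir / "lof_all.tsv")
    write_lof_tsv(result.lof_thresholded, outdir / "lof_thresholded.tsv")
    write_cnv_tsv(result.cnv, outdir / "cnv_candidates.tsv")
    write_recurrence_tsv(result.recurrence, outdir / "recurrence.tsv")
    summary = {
        "config": result.config.to_dict(),
        "counts": {
            "missense_candidates": len(result.missense),
            "lof_all": len(result.lof),
            "lof_thresholded": len(result.lof_thresholded),
            "cnv_candidates": len(result.cnv),
            "cnv_distinct_genes": len(distinct_genes(result.cnv)),
            "candidate_genes": len(result.candidate_gene_symbols()),
            "recurrent_genes": len(result.recurrence.recurrent_genes),
            "private_violations": len(result.recurrence.private_violations),
        },
        "stage_totals": {
            stage: sum(t.counts[i] for t in result.traces)
            for i, stage in enumerate(result.traces[0].stages)
        } if result.traces else {},
    }
    _audit_thresholds(result.config, summary)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
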