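"""Domain types shared across the prioritization cascade.

The pipeline operates on four kinds of objects: pedigrees (family
structure, affection status, and which members were sequenced),
annotated small variants (one alt allele per record, with a profile of
precomputed population frequencies and in-silico scores), CNV segments
with per-member carrier flags, and gene models used for CNV overlap
queries.

All genomic coordinates are 1-based and inclusive internally; BED I/O
converts at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

# ---------------------------------------------------------------------------
# exceptions

class FamseqError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FamseqError):
    """An input file violates its declared format."""


class DataError(FamseqError):
    """A value is outside its legal domain (e.g. negative allele frequency)."""


class ConsistencyError(FamseqError):
    """Cross-file or cross-stage inconsistency (samples vs pedigree, traces)."""


# ---------------------------------------------------------------------------
# controlled vocabularies

SEXES = ("male", "female", "unknown")
AFFECTIONS = ("affected", "unaffected", "unknown")
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")
CONSEQUENCES = ("missense", "frameshift", "stopgain", "splice_site", "other")
CNV_TYPES = ("duplication", "deletion")

#: The ten deleteriousness predictors consumed as categorical calls.
PREDICTORS = (
    "SIFT",
    "PolyPhen2_HDIV",
    "PolyPhen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "PROVEAN",
)

PREDICTOR_CALLS = ("deleterious", "tolerated")

#: Population allele-frequency resources recognised by default.
POPULATIONS = ("gnomad", "exac", "esp6500", "local")

#: Gene-intolerance percentile reference sets.
INTOLERANCE_SETS = ("esp6500", "exac", "local")


# ---------------------------------------------------------------------------
# pedigree

@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str = "unknown"
    affection: str = "unknown"
    sequenced: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"illegal sex {self.sex!r} for {self.individual_id}")
        if self.affection not in AFFECTIONS:
            raise DataError(
                f"illegal affection {self.affection!r} for {self.individual_id}"
            )


class Pedigree:
    """A cohort of families with affection status and sequenced flags.

    Individual ids must be unique within a family (and, for multi-sample
    variant files, are treated as unique cohort-wide). Parent references
    must resolve within the same family or be absent.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: List[Individual] = list(individuals)
        self._by_family: Dict[str, Dict[str, Individual]] = {}
        for ind in self.individuals:
            fam = self._by_family.setdefault(ind.family_id, {})
            if ind.individual_id in fam:
                raise FormatError(
                    f"duplicate individual id {ind.individual_id!r} "
                    f"in family {ind.family_id!r}"
                )
            fam[ind.individual_id] = ind
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in self._by_family[ind.family_id]:
                    raise FormatError(
                        f"parent id {parent!r} of individual "
                        f"{ind.individual_id!r} not found in family "
                        f"{ind.family_id!r}"
                    )

    @property
    def families(self) -> Tuple[str, ...]:
        return tuple(self._by_family)

    def family_members(self, family_id: str) -> List[Individual]:
        if family_id not in self._by_family:
            raise ConsistencyError(f"unknown family {family_id!r}")
        return list(self._by_family[family_id].values())

    def sequenced_members(self, family_id: str) -> List[Individual]:
        return [m for m in self.family_members(family_id) if m.sequenced]

    def individual(self, family_id: str, individual_id: str) -> Individual:
        try:
            return self._by_family[family_id][individual_id]
        except KeyError:
            raise ConsistencyError(
                f"individual {individual_id!r} not in family {family_id!r}"
            ) from None

    def affection_counts(self, family_id: str, sequenced_only: bool = False
                         ) -> Dict[str, int]:
        members = (self.sequenced_members(family_id) if sequenced_only
                   else self.family_members(family_id))
        counts = {a: 0 for a in AFFECTIONS}
        for m in members:
            counts[m.affection] += 1
        return counts

    def __len__(self) -> int:
        return len(self.individuals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self.individuals == other.individuals


# ---------------------------------------------------------------------------
# annotation profile

@dataclass
class AnnotationProfile:
    """Precomputed annotation scores and calls a variant carries.

    Every field may be missing (``None``); filters decide their own
    missing-value policy. Scores are consumed, never computed here.
    """

    pop_afs: Dict[str, float] = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    exac_z: Optional[float] = None
    intolerance_percentiles: Dict[str, float] = field(default_factory=dict)
    predictor_calls: Dict[str, str] = field(default_factory=dict)
    mutpred_lof: Optional[float] = None
    hsf_alters_splicing: Optional[str] = None  # "yes" / "no" / None

    def __post_init__(self) -> None:
        for pop, af in self.pop_afs.items():
            if af is None:
                continue
            if not 0.0 <= af <= 1.0:
                raise DataError(f"allele frequency {af} for {pop!r} outside [0,1]")
        if self.phastcons is not None and not 0.0 <= self.phastcons <= 1.0:
            raise DataError(f"PhastCons {self.phastcons} outside [0,1]")
        if self.mutpred_lof is not None and not 0.0 <= self.mutpred_lof <= 1.0:
            raise DataError(f"MutPred-LOF {self.mutpred_lof} outside [0,1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise DataError(f"CADD phred {self.cadd_phred} negative")
        bad = set(self.predictor_calls) - set(PREDICTORS)
        if bad:
            raise DataError(f"unknown predictor names: {sorted(bad)}")
        for name, call in self.predictor_calls.items():
            if call not in PREDICTOR_CALLS:
                raise DataError(f"illegal call {call!r} for predictor {name}")
        if self.hsf_alters_splicing not in (None, "yes", "no"):
            raise DataError(
                f"illegal splicing flag {self.hsf_alters_splicing!r}"
            )


# ---------------------------------------------------------------------------
# variants

VariantKey = Tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One alt allele at one locus, scoped to a single family."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str
    gene_symbol: str
    family_id: str
    genotypes: Dict[str, str]  # individual_id -> hom_ref|het|hom_alt|missing
    profile: AnnotationProfile = field(default_factory=AnnotationProfile)

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise DataError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise DataError(f"illegal consequence {self.consequence!r}")
        for gt in self.genotypes.values():
            if gt not in GENOTYPES:
                raise DataError(f"illegal genotype {gt!r} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def chrom_sort_key(chrom: str) -> Tuple[int, str]:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (int(m.group(1)), "")
    return (10**6, chrom)


def variant_sort_key(rec: VariantRecord) -> Tuple[Tuple[int, str], int, str]:
    return (chrom_sort_key(rec.chrom), rec.pos, rec.alt)


# ---------------------------------------------------------------------------
# CNV segments

@dataclass
class CNVSegment:
    """A duplication/deletion call with per-member carrier flags.

    Coordinates are 1-based inclusive; carrier status is binary
    (presence of the segment), dosage is not modelled.
    """

    family_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    carriers: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"CNV interval start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.cnv_type not in CNV_TYPES:
            raise DataError(f"illegal CNV type {self.cnv_type!r}")

    @property
    def key(self) -> Tuple[str, str, int, int, str]:
        return (self.family_id, self.chrom, self.start, self.end, self.cnv_type)


# ---------------------------------------------------------------------------
# gene models

@dataclass(frozen=True)
class GeneFeature:
    gene_symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    feature: str = "gene"  # "gene" | "coding_region"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"gene feature start > end: {self.gene_symbol} "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.feature not in ("gene", "coding_region"):
            raise DataError(f"illegal feature {self.feature!r}")


class GeneModelSet:
    """Gene features indexed for interval overlap queries.

    Genes that provide explicit ``coding_region`` features are queried on
    those; genes represented only by a ``gene`` span fall back to the
    whole span. Overlap is >= 1 base on 1-based inclusive intervals.
    """

    def __init__(self, features: Iterable[GeneFeature]):
        self.features: List[GeneFeature] = list(features)
        coding_genes = {f.gene_symbol for f in self.features
                        if f.feature == "coding_region"}
        self._trees: Dict[str, IntervalTree] = {}
        self._gene_start: Dict[str, Tuple[Tuple[int, str], int]] = {}
        for f in self.features:
            effective = (f.feature == "coding_region"
                         or f.gene_symbol not in coding_genes)
            if effective:
                tree = self._trees.setdefault(f.chrom, IntervalTree())
                # interval tree is half-open; store [start, end+1)
                tree.addi(f.start, f.end + 1, f.gene_symbol)
            key = (chrom_sort_key(f.chrom), f.start)
            if (f.gene_symbol not in self._gene_start
                    or key < self._gene_start[f.gene_symbol]):
                self._gene_start[f.gene_symbol] = key

    def overlapping_genes(self, chrom: str, start: int, end: int) -> List[str]:
        """Gene symbols with >= 1 base overlap, sorted by (chrom, start, symbol)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = {iv.data for iv in tree.overlap(start, end + 1)}
        return sorted(hits, key=lambda g: (self._gene_start[g], g))

    def __len__(self) -> int:
        return len(self.features)
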