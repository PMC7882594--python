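"""Synthetic family-cohort generator with full ground truth.

Emulates, at desk scale, the statistical structure the prioritization
cascade assumes: a cohort of ~21 pedigrees each contributing 2-4
sequenced affected and 0-2 sequenced unaffected members; per family a
background of rare-variant calls whose annotation scores follow stated
marginal distributions and whose genotypes are independent of affection
status; per family planted causal variants transmitted dominantly
(carried by every sequenced affected member, by no unaffected member);
and CNV segments, seven of which segregate while decoys do not.

Design of the marginals
-----------------------
* CADD phred for background variants is drawn as ``-10*log10(U)`` with
  U uniform on (0, 1], i.e. by the phred rank definition, so exactly 1%
  of background mass lies above 20 and the analytic gate-pass product is
  meaningful.
* Population allele frequency is log-uniform on [1e-5, 0.05] and is
  reported identically in two resources (gnomAD- and ExAC-style
  columns): the rarity gate aggregates by max, so a single latent
  frequency keeps the pass probability in closed form.
* Conservation scores are uniform on ranges bracketing their thresholds;
  the ten predictor calls are present independently (p=0.9) and
  deleterious with background probability 0.2 versus 0.9 for planted
  variants.
* Background genotypes: each sequenced member is a carrier with
  probability 0.25 regardless of affection — the null the segregation
  filter is meant to reject. Background genotypes are not constrained to
  be Mendelian-consistent within a pedigree; planted variants are, via
  seeded gene dropping.

Planted variants come in a "passing" regime (every default gate
satisfied by construction) and a "failing" regime (exactly one gate's
evidence sampled on the wrong side of its threshold), recorded per gate
in the ground truth so recovery tests can score sensitivity and leakage
exactly. Identical (spec, seed) yields an identical cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .model import (
    AnnotationProfile,
    CNVSegment,
    DataError,
    GeneFeature,
    GeneModelSet,
    Individual,
    Pedigree,
    PREDICTORS,
    VariantKey,
    VariantRecord,
)
from . import io_formats

CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_BASES = ("A", "C", "G", "T")

#: chr4 worked-example gene placements (coding spans inside the printed
#: duplication interval chr4:15936942-16178663).
CHR4_EXAMPLE_INTERVAL = ("chr4", 15_936_942, 16_178_663)
CHR4_EXAMPLE_GENES = (
    ("FGFBP1", 15_940_000, 15_955_000),
    ("FGFBP2", 15_970_000, 15_985_000),
    ("PROM1", 16_040_000, 16_090_000),
    ("TAPT1", 16_120_000, 16_170_000),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_families: int = 21
    affected_range: Tuple[int, int] = (2, 4)    # sequenced affected/family
    unaffected_range: Tuple[int, int] = (0, 2)  # sequenced unaffected/family
    background_variants: int = 1000             # per family
    planted_passing_per_family: int = 1
    planted_failing_per_family: int = 1
    n_planted_cnvs: int = 7                     # cohort-wide, segregating
    n_decoy_cnvs: int = 20                      # non-segregating
    genotype_missing_rate: float = 0.0          # background genotypes only
    seed: int = 0

    # background annotation marginals
    af_range: Tuple[float, float] = (1e-5, 0.05)     # log-uniform
    gerp_range: Tuple[float, float] = (-3.0, 6.0)    # uniform
    phastcons_range: Tuple[float, float] = (0.0, 1.0)
    phylop_range: Tuple[float, float] = (-5.0, 9.0)
    predictor_present_prob: float = 0.9
    background_deleterious_prob: float = 0.2
    planted_deleterious_prob: float = 0.9
    background_carrier_prob: float = 0.25
    hsf_yes_prob: float = 0.3
    consequence_probs: Tuple[Tuple[str, float], ...] = (
        ("missense", 0.55), ("other", 0.30), ("splice_site", 0.07),
        ("frameshift", 0.04), ("stopgain", 0.04),
    )

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise DataError("need at least one family")
        if self.affected_range[0] < 1:
            raise DataError("families need at least one sequenced affected "
                            "member (zero affected is uninterpretable)")
        if not math.isclose(sum(p for _, p in self.consequence_probs), 1.0):
            raise DataError("consequence probabilities must sum to 1")
        if not 0 <= self.genotype_missing_rate < 1:
            raise DataError("genotype_missing_rate must be in [0, 1)")


#: Passing-regime draw ranges (each gate satisfied by construction).
PASSING_REGIME = {
    "af_range": (1e-6, 5e-4),
    "cadd_rank_range": (1e-4, 5e-3),   # cadd = -10*log10(rank) in (23, 40]
    "gerp_range": (3.0, 6.0),
    "phastcons_range": (0.6, 1.0),
    "phylop_range": (4.0, 9.0),
}

#: Failing-regime draws: one gate's evidence on the wrong side.
FAILING_DRAWS = {
    "maf": ("af_range", (2e-3, 1e-2)),
    "cadd": ("cadd_rank_range", (0.05, 0.5)),       # cadd in (3, 13]
    "conservation": ("gerp_range", (-2.0, 1.5)),
    "consensus": None,   # <= 4 of 10 deleterious calls
    "segregation": None,  # one genotype flipped against co-segregation
}

GATES = ("maf", "segregation", "cadd", "conservation", "consensus")


@dataclass
class PlantedVariant:
    family_id: str
    key: VariantKey
    gene_symbol: str
    regimes: Dict[str, str]  # gate -> "passing" | "failing"

    @property
    def all_passing(self) -> bool:
        return all(r == "passing" for r in self.regimes.values())


@dataclass
class GroundTruth:
    planted_variants: List[PlantedVariant] = field(default_factory=list)
    planted_cnv_keys: List[Tuple[str, str, int, int, str]] = \
        field(default_factory=list)

    def passing_keys(self) -> List[VariantKey]:
        return [p.key for p in self.planted_variants if p.all_passing]

    def failing_keys(self) -> List[VariantKey]:
        return [p.key for p in self.planted_variants if not p.all_passing]

    def to_dict(self) -> dict:
        return {
            "planted_variants": [
                {"family_id": p.family_id, "key": list(p.key),
                 "gene_symbol": p.gene_symbol, "regimes": p.regimes}
                for p in self.planted_variants],
            "planted_cnv_keys": [list(k) for k in self.planted_cnv_keys],
        }


@dataclass
class Cohort:
    spec: CohortSpec
    pedigree: Pedigree
    variants: List[VariantRecord]
    cnv_segments: List[CNVSegment]
    gene_models: GeneModelSet
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# gene dropping

def mendelian_drop(pedigree: Union[Pedigree, Mapping[str, Tuple[Optional[str],
                                                                Optional[str]]]],
                   founder_genotypes: Mapping[str, Tuple[int, int]],
                   rng: np.random.Generator) -> Dict[str, Tuple[int, int]]:
    """Drop founder alleles through a pedigree under Mendelian transmission.

    ``pedigree`` is a :class:`Pedigree` or a mapping individual ->
    (father_id, mother_id); founders (both parents None) must appear in
    ``founder_genotypes`` as biallelic (a1, a2) tuples with alleles 0/1.
    Each child inherits one uniformly chosen allele from each parent.
    Dominant carrier status is ``sum(genotype) > 0``.
    """
    if isinstance(pedigree, Pedigree):
        parents = {ind.individual_id: (ind.father_id, ind.mother_id)
                   for ind in pedigree.individuals}
    else:
        parents = dict(pedigree)
    genotypes: Dict[str, Tuple[int, int]] = {}
    for iid, (father, mother) in parents.items():
        if father is None and mother is None:
            if iid not in founder_genotypes:
                raise DataError(f"founder {iid!r} has no assigned genotype")
            genotypes[iid] = tuple(founder_genotypes[iid])  # type: ignore

    pending = {iid for iid in parents if iid not in genotypes}
    while pending:
        progressed = False
        for iid in sorted(pending):
            father, mother = parents[iid]
            if father in genotypes and mother in genotypes:
                pat = genotypes[father][int(rng.integers(2))]
                mat = genotypes[mother][int(rng.integers(2))]
                genotypes[iid] = (pat, mat)
                pending.discard(iid)
                progressed = True
        if not progressed:
            raise DataError(
                f"unresolvable pedigree: individuals {sorted(pending)} have "
                "parents without genotypes"
            )
    return genotypes


# ---------------------------------------------------------------------------
# pedigree construction

def _make_family(family_id: str, spec: CohortSpec,
                 rng: np.random.Generator) -> List[Individual]:
    """One dominant-transmission pedigree: an affected carrier founder,
    an unaffected co-founder, children (and sometimes grandchildren via
    married-in non-carriers). Affection equals latent-allele carrier
    status (full penetrance), so planted variants co-segregate exactly.
    Redraws transmission until the family has >= 2 affected members."""
    father = f"{family_id}_I1"
    mother = f"{family_id}_I2"
    for _ in range(100):
        parents: Dict[str, Tuple[Optional[str], Optional[str]]] = {
            father: (None, None), mother: (None, None)}
        sexes = {father: "male", mother: "female"}
        founders = {father: (1, 0), mother: (0, 0)}
        counter = 3
        children = []
        for _ in range(int(rng.integers(2, 5))):
            child = f"{family_id}_I{counter}"
            counter += 1
            parents[child] = (father, mother)
            sexes[child] = "male" if rng.random() < 0.5 else "female"
            children.append(child)
        for child in children:
            if rng.random() < 0.4:
                spouse = f"{family_id}_I{counter}"
                counter += 1
                parents[spouse] = (None, None)
                founders[spouse] = (0, 0)
                sexes[spouse] = "female" if sexes[child] == "male" else "male"
                for _ in range(int(rng.integers(1, 3))):
                    gchild = f"{family_id}_I{counter}"
                    counter += 1
                    if sexes[child] == "male":
                        parents[gchild] = (child, spouse)
                    else:
                        parents[gchild] = (spouse, child)
                    sexes[gchild] = "male" if rng.random() < 0.5 else "female"
        genotypes = mendelian_drop(parents, founders, rng)
        carriers = {iid for iid, gt in genotypes.items() if sum(gt) > 0}
        if len(carriers) >= 2:
            break
    else:  # pragma: no cover - 100 redraws failing is astronomically unlikely
        raise DataError(f"could not realize >= 2 carriers in {family_id}")

    affected = sorted(carriers)
    unaffected = sorted(set(parents) - carriers)
    lo, hi = spec.affected_range
    n_aff_seq = min(int(rng.integers(lo, hi + 1)), len(affected))
    n_aff_seq = max(n_aff_seq, min(2, len(affected)))
    lo_u, hi_u = spec.unaffected_range
    n_unaff_seq = min(int(rng.integers(lo_u, hi_u + 1)), len(unaffected))
    seq_aff = set(rng.choice(affected, size=n_aff_seq, replace=False))
    seq_unaff = set(rng.choice(unaffected, size=n_unaff_seq, replace=False)) \
        if n_unaff_seq else set()

    individuals = []
    for iid in sorted(parents, key=lambda x: int(x.rsplit("_I", 1)[1])):
        f, m = parents[iid]
        individuals.append(Individual(
            individual_id=iid, family_id=family_id,
            father_id=f, mother_id=m, sex=sexes[iid],
            affection="affected" if iid in carriers else "unaffected",
            sequenced=iid in seq_aff or iid in seq_unaff,
        ))
    return individuals


# ---------------------------------------------------------------------------
# gene models

def make_gene_models(genes_per_chrom: int = 30) -> GeneModelSet:
    """Deterministic tiled gene models plus the chr4 worked-example genes.

    Tiled genes sit every 200 kb from 50 kb with a 40 kb span and a 30 kb
    coding region; the four named chr4 genes have their coding spans
    inside the worked-example duplication interval.
    """
    feats: List[GeneFeature] = []
    for chrom in CHROMS:
        for k in range(genes_per_chrom):
            start = 200_000 * k + 50_001
            end = start + 39_999
            name = f"TG{chrom[3:]}_{k}"
            feats.append(GeneFeature(name, chrom, start, end, "+", "gene"))
            feats.append(GeneFeature(name, chrom, start + 5_000, end - 5_000,
                                     "+", "coding_region"))
    for name, start, end in CHR4_EXAMPLE_GENES:
        feats.append(GeneFeature(name, "chr4", start - 2_000, end + 2_000,
                                 "+", "gene"))
        feats.append(GeneFeature(name, "chr4", start, end, "+",
                                 "coding_region"))
    return GeneModelSet(feats)


def cnv_worked_example() -> Tuple[CNVSegment, GeneModelSet]:
    """The printed chr4 duplication against the fixture gene model; its
    coding overlap is exactly the four named genes."""
    chrom, start, end = CHR4_EXAMPLE_INTERVAL
    segment = CNVSegment(family_id="Family5", chrom=chrom, start=start,
                         end=end, cnv_type="duplication", carriers={})
    return segment, make_gene_models()


# ---------------------------------------------------------------------------
# variant synthesis

def _background_records(family_id: str, members: Sequence[Individual],
                        fam_idx: int, spec: CohortSpec,
                        rng: np.random.Generator) -> List[VariantRecord]:
    n = spec.background_variants
    seq_ids = [m.individual_id for m in members if m.sequenced]
    lo, hi = spec.af_range
    af = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    cadd = -10.0 * np.log10(1.0 - rng.random(n))  # U in (0,1] by construction
    gerp = rng.uniform(*spec.gerp_range, n)
    phast = rng.uniform(*spec.phastcons_range, n)
    phylop = rng.uniform(*spec.phylop_range, n)
    classes = [c for c, _ in spec.consequence_probs]
    csq = rng.choice(len(classes), size=n,
                     p=[p for _, p in spec.consequence_probs])
    present = rng.random((n, len(PREDICTORS))) < spec.predictor_present_prob
    delet = rng.random((n, len(PREDICTORS))) < spec.background_deleterious_prob
    mutpred = rng.random(n)
    hsf_yes = rng.random(n) < spec.hsf_yes_prob
    exac_z = rng.normal(0.0, 2.0, n)
    pct_present = rng.random((n, 3)) < 0.8
    pct_vals = rng.uniform(0.0, 100.0, (n, 3))
    carrier = rng.random((n, len(seq_ids))) < spec.background_carrier_prob
    hom_alt = rng.random((n, len(seq_ids))) < 0.05
    missing = rng.random((n, len(seq_ids))) < spec.genotype_missing_rate
    gene_idx = rng.integers(0, 4000, n)
    refs = rng.integers(0, 4, n)
    alts = (refs + 1 + rng.integers(0, 3, n)) % 4

    records = []
    for i in range(n):
        consequence = classes[int(csq[i])]
        calls = {PREDICTORS[j]: ("deleterious" if delet[i, j] else "tolerated")
                 for j in range(len(PREDICTORS)) if present[i, j]}
        genotypes = {}
        for j, iid in enumerate(seq_ids):
            if missing[i, j]:
                genotypes[iid] = "missing"
            elif carrier[i, j]:
                genotypes[iid] = "hom_alt" if hom_alt[i, j] else "het"
            else:
                genotypes[iid] = "hom_ref"
        profile = AnnotationProfile(
            pop_afs={"gnomad": float(af[i]), "exac": float(af[i])},
            cadd_phred=float(cadd[i]), gerp=float(gerp[i]),
            phastcons=float(phast[i]), phylop=float(phylop[i]),
            exac_z=float(exac_z[i]),
            intolerance_percentiles={
                s: float(pct_vals[i, j])
                for j, s in enumerate(("esp6500", "exac", "local"))
                if pct_present[i, j]},
            predictor_calls=calls,
            mutpred_lof=(float(mutpred[i])
                         if consequence in ("frameshift", "stopgain") else None),
            hsf_alters_splicing=(("yes" if hsf_yes[i] else "no")
                                 if consequence == "splice_site" else None),
        )
        chrom = CHROMS[i % len(CHROMS)]
        pos = 50_000 + (i // len(CHROMS)) * 2_000 + fam_idx * 29
        records.append(VariantRecord(
            chrom=chrom, pos=pos,
            ref=_BASES[int(refs[i])], alt=_BASES[int(alts[i])],
            consequence=consequence,
            gene_symbol=f"GENE{int(gene_idx[i]):04d}",
            family_id=family_id, genotypes=genotypes, profile=profile,
        ))
    return records


def _planted_record(family_id: str, members: Sequence[Individual],
                    fam_idx: int, plant_idx: int, failing_gate: Optional[str],
                    spec: CohortSpec, rng: np.random.Generator
                    ) -> Tuple[VariantRecord, PlantedVariant]:
    """One planted missense variant; ``failing_gate`` names the single
    gate whose evidence is sampled on the wrong side (None = passing
    regime for every gate)."""
    regime = dict(PASSING_REGIME)
    af_lo, af_hi = regime["af_range"]
    if failing_gate == "maf":
        af_lo, af_hi = FAILING_DRAWS["maf"][1]
    rank_lo, rank_hi = regime["cadd_rank_range"]
    if failing_gate == "cadd":
        rank_lo, rank_hi = FAILING_DRAWS["cadd"][1]
    gerp_lo, gerp_hi = regime["gerp_range"]
    if failing_gate == "conservation":
        gerp_lo, gerp_hi = FAILING_DRAWS["conservation"][1]

    af = float(np.exp(rng.uniform(np.log(af_lo), np.log(af_hi))))
    cadd = float(-10.0 * np.log10(rng.uniform(rank_lo, rank_hi)))
    gerp = float(rng.uniform(gerp_lo, gerp_hi))
    phast = float(rng.uniform(*regime["phastcons_range"]))
    phylop = float(rng.uniform(*regime["phylop_range"]))

    if failing_gate == "consensus":
        n_del = int(rng.integers(0, 5))  # at most 4/10: below strict majority
    else:
        n_del = 0
        while n_del < 6:  # guarantee strict majority by construction
            n_del = int(rng.binomial(len(PREDICTORS),
                                     spec.planted_deleterious_prob))
    del_idx = set(rng.choice(len(PREDICTORS), size=n_del, replace=False))
    calls = {PREDICTORS[j]: ("deleterious" if j in del_idx else "tolerated")
             for j in range(len(PREDICTORS))}

    genotypes = {}
    for m in members:
        if not m.sequenced:
            continue
        genotypes[m.individual_id] = \
            "het" if m.affection == "affected" else "hom_ref"
    if failing_gate == "segregation":
        seq = [m for m in members if m.sequenced]
        unaff = [m for m in seq if m.affection == "unaffected"]
        if unaff:  # an unaffected carrier breaks the default policy
            genotypes[unaff[0].individual_id] = "het"
        else:      # no unaffected members: break the affected side instead
            aff = [m for m in seq if m.affection == "affected"]
            genotypes[aff[-1].individual_id] = "hom_ref"

    chrom = CHROMS[fam_idx % len(CHROMS)]
    pos = 9_000_000 + fam_idx * 10_000 + plant_idx * 100
    gene = (f"CAND_{family_id}" if failing_gate is None
            else f"CANDF_{family_id}_{failing_gate}")
    record = VariantRecord(
        chrom=chrom, pos=pos, ref="G", alt="A", consequence="missense",
        gene_symbol=gene, family_id=family_id, genotypes=genotypes,
        profile=AnnotationProfile(
            pop_afs={"gnomad": af, "exac": af},
            cadd_phred=cadd, gerp=gerp, phastcons=phast, phylop=phylop,
            exac_z=float(rng.uniform(1.0, 5.0)),
            intolerance_percentiles={"exac": float(rng.uniform(0.0, 20.0))},
            predictor_calls=calls, mutpred_lof=None, hsf_alters_splicing=None,
        ),
    )
    regimes = {g: ("failing" if g == failing_gate else "passing")
               for g in GATES}
    return record, PlantedVariant(family_id=family_id, key=record.key,
                                  gene_symbol=gene, regimes=regimes)


# ---------------------------------------------------------------------------
# CNV synthesis

def _planted_cnv_plan() -> List[Tuple[str, int, int, str]]:
    """Seven segregating segments jointly overlapping 11 distinct coding
    genes: the chr4 worked example (4 genes), one two-gene segment, and
    five single-gene segments."""
    chrom, start, end = CHR4_EXAMPLE_INTERVAL
    plan = [(chrom, start, end, "duplication"),
            ("chr1", 50_001, 300_000, "deletion")]        # tiles 0 and 1
    for i, c in enumerate(("chr2", "chr3", "chr5", "chr6", "chr7")):
        plan.append((c, 60_000, 70_000,
                     "duplication" if i % 2 == 0 else "deletion"))
    return plan


def _make_cnvs(pedigree: Pedigree, spec: CohortSpec,
               rng: np.random.Generator
               ) -> Tuple[List[CNVSegment], List[Tuple[str, str, int, int, str]]]:
    families = list(pedigree.families)
    order = list(rng.permutation(len(families)))
    plan = _planted_cnv_plan()[:spec.n_planted_cnvs]
    segments: List[CNVSegment] = []
    planted_keys = []
    for i, (chrom, start, end, cnv_type) in enumerate(plan):
        fam = families[order[i % len(families)]]
        carriers = {m.individual_id: m.affection == "affected"
                    for m in pedigree.sequenced_members(fam)}
        seg = CNVSegment(family_id=fam, chrom=chrom, start=start, end=end,
                         cnv_type=cnv_type, carriers=carriers)
        segments.append(seg)
        planted_keys.append(seg.key)
    for d in range(spec.n_decoy_cnvs):
        fam = families[int(rng.integers(len(families)))]
        members = pedigree.sequenced_members(fam)
        carriers = {m.individual_id: bool(rng.random() < 0.5) for m in members}
        # guarantee non-segregation: one sequenced affected non-carrier
        affected = [m for m in members if m.affection == "affected"]
        carriers[affected[int(rng.integers(len(affected)))].individual_id] \
            = False
        chrom = CHROMS[8 + d % 14]
        start = 450_000 + int(rng.integers(50)) * 200_000 + 1
        seg = CNVSegment(family_id=fam, chrom=chrom, start=start,
                         end=start + int(rng.integers(10_000, 150_000)),
                         cnv_type="duplication" if rng.random() < 0.5
                         else "deletion", carriers=carriers)
        segments.append(seg)
    return segments, planted_keys


# ---------------------------------------------------------------------------
# top level

def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate a full synthetic cohort; deterministic in (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    individuals: List[Individual] = []
    family_ids = [f"F{i+1:02d}" for i in range(spec.n_families)]
    for fam in family_ids:
        individuals.extend(_make_family(fam, spec, rng))
    pedigree = Pedigree(individuals)

    truth = GroundTruth()
    variants: List[VariantRecord] = []
    gate_cycle = [g for g in GATES]
    for fam_idx, fam in enumerate(family_ids):
        members = pedigree.family_members(fam)
        plant_idx = 0
        for _ in range(spec.planted_passing_per_family):
            rec, planted = _planted_record(fam, members, fam_idx, plant_idx,
                                           None, spec, rng)
            variants.append(rec)
            truth.planted_variants.append(planted)
            plant_idx += 1
        for k in range(spec.planted_failing_per_family):
            gate = gate_cycle[(fam_idx + k) % len(gate_cycle)]
            rec, planted = _planted_record(fam, members, fam_idx, plant_idx,
                                           gate, spec, rng)
            variants.append(rec)
            truth.planted_variants.append(planted)
            plant_idx += 1
        variants.extend(
            _background_records(fam, members, fam_idx, spec, rng))

    gene_models = make_gene_models()
    cnv_segments, planted_cnv_keys = _make_cnvs(pedigree, spec, rng)
    truth.planted_cnv_keys = planted_cnv_keys
    return Cohort(spec=spec, pedigree=pedigree, variants=variants,
                  cnv_segments=cnv_segments, gene_models=gene_models,
                  ground_truth=truth)


def write_cohort(cohort: Cohort, outdir: Union[str, Path],
                 vcf: bool = False) -> Dict[str, Path]:
    """Write a cohort to disk (PED, variant TSV, CNV BED, gene-model BED,
    ground-truth JSON; optionally a VCF)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "cohort.ped",
        "variants": outdir / "variants.tsv",
        "cnvs": outdir / "cnv_segments.bed",
        "genes": outdir / "gene_models.bed",
        "ground_truth": outdir / "ground_truth.json",
    }
    io_formats.write_pedigree(cohort.pedigree, paths["pedigree"])
    io_formats.write_variants(cohort.variants, paths["variants"])
    io_formats.write_cnv_segments(cohort.cnv_segments, paths["cnvs"])
    io_formats.write_gene_models(cohort.gene_models, paths["genes"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(cohort.ground_truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    if vcf:
        paths["vcf"] = outdir / "variants.vcf"
        io_formats.write_variants_vcf(cohort.variants, paths["vcf"])
    return paths


# ---------------------------------------------------------------------------
# analytic null expectations (for false-positive calibration checks)

def p_maf_pass(spec: CohortSpec = CohortSpec(),
               threshold: float = 0.001) -> float:
    """P(background variant passes the rarity gate) under the log-uniform
    allele-frequency marginal (both resources report the same latent AF)."""
    lo, hi = spec.af_range
    if threshold <= lo:
        return 0.0
    if threshold >= hi:
        return 1.0
    return math.log(threshold / lo) / math.log(hi / lo)


def p_cadd_pass(threshold: float = 20.0) -> float:
    """P(background CADD > threshold) = 10^(-t/10) by the phred-rank
    construction."""
    return 10.0 ** (-threshold / 10.0)


def p_segregation_pass(n_affected: int, n_unaffected: int,
                       spec: CohortSpec = CohortSpec(),
                       max_unaffected_carriers: int = 0) -> float:
    """P(background genotypes co-segregate) with iid carrier draws."""
    p = spec.background_carrier_prob
    p_unaff = float(stats.binom.cdf(max_unaffected_carriers, n_unaffected, p)) \
        if n_unaffected else 1.0
    return p ** n_affected * p_unaff


def p_conservation_pass(spec: CohortSpec = CohortSpec()) -> float:
    """P(background conservation profile passes all three gates)."""
    def frac_above(rng_pair, cut, inclusive=False):
        lo, hi = rng_pair
        x = max(min(cut, hi), lo)
        return (hi - x) / (hi - lo)

    return (frac_above(spec.gerp_range, 2.0)
            * frac_above(spec.phastcons_range, 0.3)
            * frac_above(spec.phylop_range, 3.0))


def p_consensus_pass(spec: CohortSpec = CohortSpec(),
                     min_fraction: float = 0.5,
                     min_calls: int = 5) -> float:
    """P(strict-majority consensus passes) under independent call
    presence/deleteriousness, by exact enumeration."""
    m = len(PREDICTORS)
    total = 0.0
    for n_avail in range(min_calls, m + 1):
        p_n = stats.binom.pmf(n_avail, m, spec.predictor_present_prob)
        k_min = math.floor(min_fraction * n_avail) + 1
        total += p_n * float(stats.binom.sf(k_min - 1, n_avail,
                                            spec.background_deleterious_prob))
    return total


def null_shared_gate_moments(pedigree: Pedigree,
                             spec: CohortSpec = CohortSpec()
                             ) -> Tuple[float, float]:
    """Mean and SD of the number of *background* variants surviving the
    shared gates (rarity AND segregation AND CADD) across the cohort."""
    mean = var = 0.0
    for fam in pedigree.families:
        counts = pedigree.affection_counts(fam, sequenced_only=True)
        p = (p_maf_pass(spec)
             * p_segregation_pass(counts["affected"], counts["unaffected"],
                                  spec)
             * p_cadd_pass())
        mean += spec.background_variants * p
        var += spec.background_variants * p * (1 - p)
    return mean, math.sqrt(var)


# ---------------------------------------------------------------------------
# small deterministic benchmark fixtures (synthetic stand-ins shaped like
# a familial-cancer candidate set)

def lof_benchmark_panel(seed: int = 0) -> List[VariantRecord]:
    """Synthetic 36-record LoF panel: 14 frameshift (2 scoring above the
    MutPred-LOF threshold), 14 stopgain (6 above), and 8 splice-site
    records (5 flagged "yes"). Incidental values are seeded draws; the
    class/threshold structure is fixed by construction.
    """
    rng = np.random.default_rng(seed)
    specs = (
        [("frameshift", "high")] * 2 + [("frameshift", "low")] * 12
        + [("stopgain", "high")] * 6 + [("stopgain", "low")] * 8
        + [("splice_site", "yes")] * 5 + [("splice_site", "no")] * 3
    )
    records = []
    for i, (csq, level) in enumerate(specs):
        fam = f"F{(i % 21) + 1:02d}"
        if csq == "splice_site":
            mutpred, hsf = None, level
        else:
            mutpred = float(rng.uniform(0.55, 0.95)) if level == "high" \
                else float(rng.uniform(0.05, 0.45))
            hsf = None
        records.append(VariantRecord(
            chrom=CHROMS[i % len(CHROMS)], pos=1_000_000 + i * 1_000,
            ref="C", alt="T", consequence=csq,
            gene_symbol=f"LOFG{i:02d}", family_id=fam, genotypes={},
            profile=AnnotationProfile(
                pop_afs={"gnomad": float(rng.uniform(1e-6, 5e-4))},
                cadd_phred=float(rng.uniform(22.0, 45.0)),
                mutpred_lof=mutpred, hsf_alters_splicing=hsf,
            ),
        ))
    return records


def recurrence_benchmark_candidates() -> List[Tuple[str, str, VariantKey]]:
    """Synthetic candidate set with the cross-family recurrence pattern:
    two genes each hit by *different* variants in two unrelated families
    (KIF1B in families 10 and 18, DCHS1 in 15 and 17), all other
    candidates private to one family."""
    return [
        ("F10", "KIF1B", ("chr1", 10_210_000, "C", "T")),
        ("F18", "KIF1B", ("chr1", 10_330_000, "G", "A")),
        ("F15", "DCHS1", ("chr11", 6_650_000, "A", "G")),
        ("F17", "DCHS1", ("chr11", 6_640_000, "C", "A")),
        ("F01", "DAB2IP", ("chr9", 124_500_000, "G", "T")),
        ("F02", "ABL2", ("chr1", 179_100_000, "T", "C")),
        ("F03", "SAMHD1", ("chr20", 36_900_000, "C", "G")),
    ]
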