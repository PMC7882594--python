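"""Readers and writers for the external formats the cascade touches.

Formats
-------
* Pedigree: whitespace-delimited PED with the usual six columns
  (family, individual, father, mother, sex, affection) plus an optional
  seventh 0/1 column flagging sequenced members (absent => all sequenced).
* Variants: flat TSV with a header (canonical dialect, lossless round
  trip) or VCF v4.x with annotations in INFO keys (via pysam).
* CNV segments and gene models: BED-like, 0-based half-open on disk,
  converted to the internal 1-based inclusive convention on read.

Column names are remappable through a key-map config so externally
annotated tables (e.g. ANNOVAR/dbNSFP exports) can be consumed without
rewriting headers. Missing values are kept missing, never imputed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Union

from .model import (
    AFFECTIONS,
    AnnotationProfile,
    CNVSegment,
    CNV_TYPES,
    ConsistencyError,
    DataError,
    FormatError,
    GeneFeature,
    GeneModelSet,
    INTOLERANCE_SETS,
    Individual,
    Pedigree,
    PREDICTORS,
    VariantRecord,
    variant_sort_key,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# vocabulary normalization tables (overridable by callers)

#: Native predictor labels -> {deleterious, tolerated}. Keys are lower-cased.
#: Covers the dbNSFP-style single-letter codes and spelled-out labels of the
#: ten predictors; unknown labels raise.
PREDICTOR_LABEL_MAP: Dict[str, str] = {
    # generic
    "deleterious": "deleterious", "damaging": "deleterious",
    "tolerated": "tolerated", "benign": "tolerated", "neutral": "tolerated",
    # SIFT / FATHMM / PROVEAN / MetaSVM / MetaLR / LRT
    "d": "deleterious", "t": "tolerated", "n": "tolerated", "u": "tolerated",
    # PolyPhen-2
    "probably_damaging": "deleterious", "possibly_damaging": "deleterious",
    "p": "deleterious", "b": "tolerated",
    # MutationTaster (A: disease_causing_automatic, D: disease_causing)
    "a": "deleterious", "disease_causing": "deleterious",
    "disease_causing_automatic": "deleterious",
    "polymorphism": "tolerated", "polymorphism_automatic": "tolerated",
    # MutationAssessor (H/M functional, L/N not)
    "h": "deleterious", "m": "deleterious", "l": "tolerated",
    "high": "deleterious", "medium": "deleterious", "low": "tolerated",
}

CONSEQUENCE_MAP: Dict[str, str] = {
    "missense": "missense", "missense_variant": "missense",
    "nonsynonymous_snv": "missense",
    "frameshift": "frameshift", "frameshift_variant": "frameshift",
    "frameshift_insertion": "frameshift", "frameshift_deletion": "frameshift",
    "stopgain": "stopgain", "stop_gained": "stopgain", "nonsense": "stopgain",
    "splice_site": "splice_site", "splice_donor_variant": "splice_site",
    "splice_acceptor_variant": "splice_site", "splicing": "splice_site",
    "other": "other",
}

GENOTYPE_MAP: Dict[str, str] = {
    "hom_ref": "hom_ref", "het": "het", "hom_alt": "hom_alt",
    "missing": "missing",
    "0/0": "hom_ref", "0|0": "hom_ref",
    "0/1": "het", "1/0": "het", "0|1": "het", "1|0": "het",
    "1/1": "hom_alt", "1|1": "hom_alt",
    "./.": "missing", ".|.": "missing", ".": "missing", "": "missing",
}

#: Default column/INFO-key map for the TSV and VCF dialects.
DEFAULT_KEY_MAP: Dict[str, object] = {
    "columns": {
        "family": "family", "chrom": "chrom", "pos": "pos",
        "ref": "ref", "alt": "alt", "gene": "gene",
        "consequence": "consequence",
        "cadd_phred": "CADD_phred", "gerp": "GERP",
        "phastcons": "PhastCons", "phylop": "PhyloP",
        "exac_z": "ExAC_Z", "mutpred_lof": "MutPred_LOF", "hsf": "HSF",
    },
    "af_prefix": "AF_",         # AF_gnomad, AF_exac, ...
    "pct_prefix": "PCT_",       # PCT_esp6500, PCT_exac, PCT_local
    "gt_prefix": "GT_",         # GT_<individual_id>  (TSV dialect only)
    "predictors": {name: name for name in PREDICTORS},
}


def merged_key_map(key_map: Optional[Dict[str, object]]) -> Dict[str, object]:
    merged: Dict[str, object] = {
        "columns": dict(DEFAULT_KEY_MAP["columns"]),
        "af_prefix": DEFAULT_KEY_MAP["af_prefix"],
        "pct_prefix": DEFAULT_KEY_MAP["pct_prefix"],
        "gt_prefix": DEFAULT_KEY_MAP["gt_prefix"],
        "predictors": dict(DEFAULT_KEY_MAP["predictors"]),
    }
    if key_map:
        for key, value in key_map.items():
            if key in ("columns", "predictors"):
                merged[key].update(value)  # type: ignore[union-attr]
            elif key in ("af_prefix", "pct_prefix", "gt_prefix"):
                merged[key] = value
            else:
                raise FormatError(f"unknown key_map entry {key!r}")
    return merged


# ---------------------------------------------------------------------------
# pedigree

_PED_SEX = {"1": "male", "2": "female", "0": "unknown", "-9": "unknown"}
_PED_AFF = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_SEX_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFF_PED = {"affected": "2", "unaffected": "1", "unknown": "0"}


def read_pedigree(path: Union[str, Path]) -> Pedigree:
    """Read a PED file (6 or 7 whitespace-delimited columns).

    The optional 7th column is a 0/1 "sequenced" flag; when absent every
    member is taken as sequenced. Raises :class:`FormatError` naming the
    offending line on duplicate ids or unresolvable parent references.
    """
    individuals: List[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (6, 7):
                raise FormatError(
                    f"{path}:{lineno}: expected 6 or 7 columns, got {len(fields)}"
                )
            fam, iid, father, mother, sex, aff = fields[:6]
            sequenced = True
            if len(fields) == 7:
                if fields[6] not in ("0", "1"):
                    raise FormatError(
                        f"{path}:{lineno}: sequenced flag must be 0 or 1, "
                        f"got {fields[6]!r}"
                    )
                sequenced = fields[6] == "1"
            individuals.append(Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if father in ("0", ".", "-9") else father,
                mother_id=None if mother in ("0", ".", "-9") else mother,
                sex=_PED_SEX.get(sex, "unknown"),
                affection=_PED_AFF.get(aff, "unknown"),
                sequenced=sequenced,
            ))
    try:
        return Pedigree(individuals)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_pedigree(pedigree: Pedigree, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            fh.write("\t".join([
                ind.family_id, ind.individual_id,
                ind.father_id or "0", ind.mother_id or "0",
                _SEX_PED[ind.sex], _AFF_PED[ind.affection],
                "1" if ind.sequenced else "0",
            ]) + "\n")


# ---------------------------------------------------------------------------
# variants: TSV dialect

def _fmt(value: Optional[float]) -> str:
    # repr is the shortest lossless rendering, so TSV round trips bit-exactly
    if value is None:
        return ""
    return repr(float(value))


def _parse_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", ".", "NA", "nan", "NaN"):
        return None
    return float(cell)


def variant_tsv_header(sample_ids: Sequence[str],
                       key_map: Optional[Dict[str, object]] = None) -> List[str]:
    km = merged_key_map(key_map)
    cols = km["columns"]
    header = [cols["family"], cols["chrom"], cols["pos"], cols["ref"],
              cols["alt"], cols["gene"], cols["consequence"]]
    header += [f"{km['af_prefix']}{p}" for p in ("gnomad", "exac", "esp6500", "local")]
    header += [cols["cadd_phred"], cols["gerp"], cols["phastcons"],
               cols["phylop"], cols["exac_z"]]
    header += [f"{km['pct_prefix']}{s}" for s in INTOLERANCE_SETS]
    header += [km["predictors"][p] for p in PREDICTORS]
    header += [cols["mutpred_lof"], cols["hsf"]]
    header += [f"{km['gt_prefix']}{s}" for s in sample_ids]
    return header


def write_variants(records: Sequence[VariantRecord], path: Union[str, Path],
                   key_map: Optional[Dict[str, object]] = None) -> None:
    """Write records as a flat TSV (the canonical lossless dialect).

    Genotype columns cover every individual genotyped in any record; a
    blank genotype cell means "not genotyped for this record's family",
    while an explicit ``missing`` marks a failed call.
    """
    km = merged_key_map(key_map)
    sample_ids = sorted({s for r in records for s in r.genotypes})
    header = variant_tsv_header(sample_ids, key_map)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            p = rec.profile
            row = [rec.family_id, rec.chrom, str(rec.pos), rec.ref, rec.alt,
                   rec.gene_symbol, rec.consequence]
            row += [_fmt(p.pop_afs.get(pop))
                    for pop in ("gnomad", "exac", "esp6500", "local")]
            row += [_fmt(p.cadd_phred), _fmt(p.gerp), _fmt(p.phastcons),
                    _fmt(p.phylop), _fmt(p.exac_z)]
            row += [_fmt(p.intolerance_percentiles.get(s))
                    for s in INTOLERANCE_SETS]
            row += [p.predictor_calls.get(name, "") for name in PREDICTORS]
            row += [_fmt(p.mutpred_lof), p.hsf_alters_splicing or ""]
            row += [rec.genotypes.get(s, "") for s in sample_ids]
            fh.write("\t".join(row) + "\n")


def _normalize_predictor_call(raw: str,
                              label_map: Dict[str, str]) -> Optional[str]:
    raw = raw.strip()
    if raw in ("", ".", "NA"):
        return None
    call = label_map.get(raw.lower())
    if call is None:
        raise FormatError(f"unknown predictor label {raw!r}")
    return call


def _read_variants_tsv(path: Union[str, Path],
                       key_map: Optional[Dict[str, object]],
                       pedigree: Optional[Pedigree],
                       label_map: Dict[str, str],
                       stats: Dict[str, int]) -> List[VariantRecord]:
    km = merged_key_map(key_map)
    cols = km["columns"]
    af_prefix, pct_prefix, gt_prefix = (
        km["af_prefix"], km["pct_prefix"], km["gt_prefix"])
    pred_by_col = {col: name for name, col in km["predictors"].items()}

    records: List[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        index = {name: i for i, name in enumerate(header)}
        required = [cols[k] for k in
                    ("family", "chrom", "pos", "ref", "alt", "gene",
                     "consequence")]
        missing_cols = [c for c in required if c not in index]
        if missing_cols:
            raise FormatError(
                f"{path}: missing required columns {missing_cols}"
            )
        gt_cols = [(name[len(gt_prefix):], i) for name, i in index.items()
                   if name.startswith(gt_prefix)]
        if pedigree is not None:
            known = {ind.individual_id for ind in pedigree.individuals}
            unknown = [s for s, _ in gt_cols if s not in known]
            if unknown:
                raise ConsistencyError(
                    f"{path}: genotype columns for samples not in pedigree: "
                    f"{sorted(unknown)}"
                )
            fam_of = {ind.individual_id: ind.family_id
                      for ind in pedigree.individuals}

        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            stats["rows"] += 1
            cells = line.rstrip("\n").split("\t")
            if len(cells) < len(header):
                cells += [""] * (len(header) - len(cells))

            def cell(col: str) -> str:
                i = index.get(col)
                return cells[i] if i is not None else ""

            def num(col: str) -> Optional[float]:
                try:
                    return _parse_float(cell(col))
                except ValueError:
                    stats["malformed_numeric"] += 1
                    logger.warning("%s:%d: unparseable numeric %r in column %s",
                                   path, lineno, cell(col), col)
                    return None

            raw_csq = cell(cols["consequence"]).strip()
            consequence = CONSEQUENCE_MAP.get(raw_csq.lower())
            if consequence is None:
                stats["unknown_consequence"] += 1
                logger.warning("%s:%d: unknown consequence %r mapped to 'other'",
                               path, lineno, raw_csq)
                consequence = "other"

            pop_afs = {}
            for name, i in index.items():
                if name.startswith(af_prefix):
                    af = num(name)
                    if af is not None:
                        pop_afs[name[len(af_prefix):]] = af
            percentiles = {}
            for s in INTOLERANCE_SETS:
                val = num(f"{pct_prefix}{s}")
                if val is not None:
                    percentiles[s] = val
            calls = {}
            for name, i in index.items():
                if name in pred_by_col:
                    call = _normalize_predictor_call(cells[i], label_map)
                    if call is not None:
                        calls[pred_by_col[name]] = call
            hsf = cell(cols["hsf"]).strip().lower() or None
            if hsf not in (None, "yes", "no"):
                raise FormatError(f"{path}:{lineno}: illegal HSF flag {hsf!r}")

            family_id = cell(cols["family"])
            genotypes: Dict[str, str] = {}
            for sample, i in gt_cols:
                raw_gt = cells[i].strip()
                if raw_gt == "":
                    continue  # sample not genotyped for this record
                if pedigree is not None and fam_of[sample] != family_id:
                    raise ConsistencyError(
                        f"{path}:{lineno}: genotype for {sample!r} but record "
                        f"belongs to family {family_id!r}"
                    )
                gt = GENOTYPE_MAP.get(raw_gt)
                if gt is None:
                    raise FormatError(
                        f"{path}:{lineno}: illegal genotype {raw_gt!r}"
                    )
                genotypes[sample] = gt

            try:
                pos = int(cell(cols["pos"]))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: position {cell(cols['pos'])!r} "
                    "is not an integer"
                ) from None
            records.append(VariantRecord(
                chrom=cell(cols["chrom"]), pos=pos,
                ref=cell(cols["ref"]), alt=cell(cols["alt"]),
                consequence=consequence, gene_symbol=cell(cols["gene"]),
                family_id=family_id, genotypes=genotypes,
                profile=AnnotationProfile(
                    pop_afs=pop_afs, cadd_phred=num(cols["cadd_phred"]),
                    gerp=num(cols["gerp"]), phastcons=num(cols["phastcons"]),
                    phylop=num(cols["phylop"]), exac_z=num(cols["exac_z"]),
                    intolerance_percentiles=percentiles,
                    predictor_calls=calls,
                    mutpred_lof=num(cols["mutpred_lof"]),
                    hsf_alters_splicing=hsf,
                ),
            ))
    return records


# ---------------------------------------------------------------------------
# variants: VCF dialect (pysam)

_GT_TUPLES = {
    (0, 0): "hom_ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom_alt",
    (None, None): "missing", (None,): "missing",
}


def _read_variants_vcf(path: Union[str, Path],
                       key_map: Optional[Dict[str, object]],
                       pedigree: Optional[Pedigree],
                       label_map: Dict[str, str],
                       stats: Dict[str, int]) -> List[VariantRecord]:
    import pysam

    km = merged_key_map(key_map)
    cols = km["columns"]
    af_prefix, pct_prefix = km["af_prefix"], km["pct_prefix"]

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    fam_of: Dict[str, str] = {}
    if pedigree is not None:
        known = {ind.individual_id for ind in pedigree.individuals}
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ConsistencyError(
                f"{path}: VCF samples not in pedigree: {sorted(unknown)}"
            )
        fam_of = {ind.individual_id: ind.family_id
                  for ind in pedigree.individuals}

    def info_num(rec, key: str) -> Optional[float]:
        if key not in rec.info:
            return None
        val = rec.info[key]
        if isinstance(val, tuple):
            val = val[0]
        try:
            return None if val is None else float(val)
        except (TypeError, ValueError):
            stats["malformed_numeric"] += 1
            return None

    def info_str(rec, key: str) -> Optional[str]:
        if key not in rec.info:
            return None
        val = rec.info[key]
        if isinstance(val, tuple):
            val = val[0]
        return None if val in (None, ".", "") else str(val)

    records: List[VariantRecord] = []
    for rec in vcf:
        stats["rows"] += 1
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(
                f"{path}: record at {rec.chrom}:{rec.pos} is not normalized "
                "to one alt allele"
            )
        family_id = info_str(rec, "FAMILY") or ""
        raw_csq = info_str(rec, cols["consequence"].upper()
                           if cols["consequence"] == "consequence"
                           else cols["consequence"]) or \
            info_str(rec, "CSQ_CLASS") or info_str(rec, "CONSEQUENCE") or ""
        consequence = CONSEQUENCE_MAP.get(raw_csq.lower())
        if consequence is None:
            stats["unknown_consequence"] += 1
            consequence = "other"

        pop_afs = {}
        for key in rec.info.keys():
            if key.startswith(af_prefix):
                af = info_num(rec, key)
                if af is not None:
                    pop_afs[key[len(af_prefix):].lower()] = af
        percentiles = {}
        for s in INTOLERANCE_SETS:
            val = info_num(rec, f"{pct_prefix}{s}")
            if val is not None:
                percentiles[s] = val
        calls = {}
        for name, key in km["predictors"].items():
            raw = info_str(rec, key)
            if raw is not None:
                call = _normalize_predictor_call(raw, label_map)
                if call is not None:
                    calls[name] = call
        hsf = info_str(rec, cols["hsf"])
        hsf = hsf.lower() if hsf else None

        genotypes: Dict[str, str] = {}
        for sample in samples:
            if pedigree is not None and family_id and \
                    fam_of.get(sample) != family_id:
                continue
            gt = rec.samples[sample].get("GT")
            genotypes[sample] = _GT_TUPLES.get(tuple(gt or (None, None)),
                                               "missing")

        records.append(VariantRecord(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
            consequence=consequence,
            gene_symbol=info_str(rec, "GENE") or "",
            family_id=family_id, genotypes=genotypes,
            profile=AnnotationProfile(
                pop_afs=pop_afs,
                cadd_phred=info_num(rec, cols["cadd_phred"]),
                gerp=info_num(rec, cols["gerp"]),
                phastcons=info_num(rec, cols["phastcons"]),
                phylop=info_num(rec, cols["phylop"]),
                exac_z=info_num(rec, cols["exac_z"]),
                intolerance_percentiles=percentiles,
                predictor_calls=calls,
                mutpred_lof=info_num(rec, cols["mutpred_lof"]),
                hsf_alters_splicing=hsf,
            ),
        ))
    return records


_GT_BACK = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1),
            "missing": (None, None)}


def write_variants_vcf(records: Sequence[VariantRecord],
                       path: Union[str, Path],
                       key_map: Optional[Dict[str, object]] = None) -> None:
    """Write records as an uncompressed single-alt VCF v4.2 (pysam)."""
    import pysam

    km = merged_key_map(key_map)
    cols = km["columns"]
    header = pysam.VariantHeader()
    chroms = []
    for rec in records:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    for chrom in sorted(chroms, key=lambda c: c):
        header.contigs.add(chrom, length=2**29)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("FAMILY", 1, "String", "Family the record is scoped to")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CONSEQUENCE", 1, "String", "Consequence class")
    for pop in ("gnomad", "exac", "esp6500", "local"):
        header.info.add(f"{km['af_prefix']}{pop}", 1, "Float",
                        f"{pop} allele frequency")
    for key in ("cadd_phred", "gerp", "phastcons", "phylop", "exac_z",
                "mutpred_lof"):
        header.info.add(cols[key], 1, "Float", key)
    for s in INTOLERANCE_SETS:
        header.info.add(f"{km['pct_prefix']}{s}", 1, "Float",
                        f"intolerance percentile ({s})")
    for name in PREDICTORS:
        header.info.add(km["predictors"][name], 1, "String",
                        f"{name} call")
    header.info.add(cols["hsf"], 1, "String", "splicing-motif flag")
    sample_ids = sorted({s for r in records for s in r.genotypes})
    for s in sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            p = rec.profile
            v = out.new_record(contig=rec.chrom, start=rec.pos - 1,
                               stop=rec.pos - 1 + len(rec.ref),
                               alleles=(rec.ref, rec.alt))
            v.info["FAMILY"] = rec.family_id
            v.info["GENE"] = rec.gene_symbol
            v.info["CONSEQUENCE"] = rec.consequence
            for pop, af in p.pop_afs.items():
                v.info[f"{km['af_prefix']}{pop}"] = af
            for key, val in (("cadd_phred", p.cadd_phred), ("gerp", p.gerp),
                             ("phastcons", p.phastcons), ("phylop", p.phylop),
                             ("exac_z", p.exac_z),
                             ("mutpred_lof", p.mutpred_lof)):
                if val is not None:
                    v.info[cols[key]] = val
            for s, val in p.intolerance_percentiles.items():
                v.info[f"{km['pct_prefix']}{s}"] = val
            for name, call in p.predictor_calls.items():
                v.info[km["predictors"][name]] = call
            if p.hsf_alters_splicing is not None:
                v.info[cols["hsf"]] = p.hsf_alters_splicing
            for s in sample_ids:
                if s in rec.genotypes:
                    v.samples[s]["GT"] = _GT_BACK[rec.genotypes[s]]
            out.write(v)


def read_variants(path: Union[str, Path], dialect: str = "tsv",
                  key_map: Optional[Dict[str, object]] = None,
                  pedigree: Optional[Pedigree] = None,
                  label_map: Optional[Dict[str, str]] = None,
                  stats: Optional[Dict[str, int]] = None
                  ) -> List[VariantRecord]:
    """Read annotated variants from TSV or VCF into domain records.

    Unparseable numeric cells become missing values and are counted in
    ``stats["malformed_numeric"]``; unknown consequence strings map to
    ``other`` and are counted in ``stats["unknown_consequence"]``. No row
    is ever silently dropped: ``stats["rows"] == len(result)``.
    """
    if stats is None:
        stats = {}
    stats.update({"rows": 0, "malformed_numeric": 0, "unknown_consequence": 0})
    lm = dict(PREDICTOR_LABEL_MAP)
    if label_map:
        lm.update({k.lower(): v for k, v in label_map.items()})
    if dialect == "tsv":
        records = _read_variants_tsv(path, key_map, pedigree, lm, stats)
    elif dialect == "vcf":
        records = _read_variants_vcf(path, key_map, pedigree, lm, stats)
    else:
        raise FormatError(f"unknown variant dialect {dialect!r}")
    if stats["malformed_numeric"]:
        logger.warning("%s: %d unparseable numeric fields set to missing",
                       path, stats["malformed_numeric"])
    return records


# ---------------------------------------------------------------------------
# CNV segments (BED-like, 0-based half-open on disk)

def read_cnv_segments(path: Union[str, Path]) -> List[CNVSegment]:
    """Read CNV calls from a BED-like table.

    Columns: chrom, start (0-based), end (half-open), family, type
    (duplication|deletion), carrier sample ids (comma list or "."),
    non-carrier sample ids (comma list or "."). Coordinates convert to
    1-based inclusive; a zero-length BED interval is a format error.
    """
    segments: List[CNVSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            chrom, start0, end0, family, cnv_type, carr, noncarr = fields[:7]
            start, end = int(start0) + 1, int(end0)
            if start > end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{chrom}:{start0}-{end0}"
                )
            if cnv_type not in CNV_TYPES:
                raise FormatError(
                    f"{path}:{lineno}: illegal CNV type {cnv_type!r}"
                )
            carriers: Dict[str, bool] = {}
            for sid in carr.split(","):
                if sid and sid != ".":
                    carriers[sid] = True
            for sid in noncarr.split(","):
                if sid and sid != ".":
                    carriers[sid] = False
            segments.append(CNVSegment(
                family_id=family, chrom=chrom, start=start, end=end,
                cnv_type=cnv_type, carriers=carriers,
            ))
    return segments


def write_cnv_segments(segments: Sequence[CNVSegment],
                       path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            carr = sorted(s for s, flag in seg.carriers.items() if flag)
            noncarr = sorted(s for s, flag in seg.carriers.items() if not flag)
            fh.write("\t".join([
                seg.chrom, str(seg.start - 1), str(seg.end), seg.family_id,
                seg.cnv_type, ",".join(carr) or ".",
                ",".join(noncarr) or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# gene models

def read_gene_models(path: Union[str, Path], dialect: str = "bed"
                     ) -> GeneModelSet:
    """Read gene models from BED (chrom, start, end, gene, feature, strand)
    or GFF3 (gene / CDS features with gene_name|Name|ID attributes)."""
    features: List[GeneFeature] = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected >= 4 columns"
                    )
                chrom, start0, end0, gene = fields[:4]
                feature = fields[4] if len(fields) > 4 and fields[4] else "gene"
                strand = fields[5] if len(fields) > 5 and fields[5] else "+"
                start, end = int(start0) + 1, int(end0)
                if start > end:
                    raise FormatError(
                        f"{path}:{lineno}: empty or inverted interval"
                    )
                features.append(GeneFeature(
                    gene_symbol=gene, chrom=chrom, start=start, end=end,
                    strand=strand, feature=feature,
                ))
    elif dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 columns")
                chrom, _src, ftype, start, end, _score, strand, _ph, attrs \
                    = fields
                if ftype not in ("gene", "CDS"):
                    continue
                attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                gene = attr.get("gene_name") or attr.get("Name") \
                    or attr.get("ID")
                if gene is None:
                    raise FormatError(
                        f"{path}:{lineno}: no gene name attribute"
                    )
                features.append(GeneFeature(
                    gene_symbol=gene, chrom=chrom,
                    start=int(start), end=int(end),  # GFF3 is 1-based inclusive
                    strand=strand if strand in "+-" else "+",
                    feature="gene" if ftype == "gene" else "coding_region",
                ))
    else:
        raise FormatError(f"unknown gene-model dialect {dialect!r}")
    return GeneModelSet(features)


def write_gene_models(genes: GeneModelSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for f in genes.features:
            fh.write("\t".join([
                f.chrom, str(f.start - 1), str(f.end), f.gene_symbol,
                f.feature, f.strand,
            ]) + "\n")
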