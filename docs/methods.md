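# Methods

## The prioritization model

`famseq` assumes a fully penetrant (or near-penetrant) dominant rare
germline allele shared by the affected members of each family. Under
that model a causal variant must be (a) rare in reference populations —
a high-penetrance allele cannot be common; (b) carried by every
sequenced affected member and, ideally, by no sequenced unaffected
member; and (c) plausibly functional, screened first by CADD and then by
consequence-specific evidence. The cascade is a conjunction of
per-variant predicates, so its stages commute mathematically; the fixed
reporting order (rarity → segregation → CADD → track gates) exists for
diagnosability of the per-family attrition trace, not for correctness.

Stages are deliberately conservative about throwing data away:
intolerance evidence and the needs-review strata annotate rather than
filter by default, and both the full and the score-thresholded LoF lists
are emitted.

## Gate semantics and defaults

| gate | rule | default | boundary |
|---|---|---|---|
| rarity | max over present population AFs | < 0.001 | strict |
| rarity, no AF present | kept (`treat_as_rare`) | — | a never-observed allele is rare by construction |
| segregation | all sequenced affected carry; ≤ k unaffected carry | k = 0 | carrier = het or hom-alt |
| CADD | phred | > 20 | strict |
| GERP / PhastCons / PhyloP | every *present* score must pass | > 2.0 / > 0.3 / ≥ 3.0 | as printed for these scores; all-missing fails (no evidence) |
| predictor consensus | deleterious fraction of non-missing calls | > 0.5 with ≥ 5 calls | strict majority; < 5 calls → needs-review stratum |
| intolerance | ExAC Z > 0 or any percentile ≤ 25 | annotate only | hard filter is opt-in (`intolerance_filter`) |
| MutPred-LOF | score | > 0.50 | strict; missing → needs-review |
| splice | motif flag | = yes | missing → needs-review |
| CNV overlap | coding-region overlap | ≥ 1 base | optional minimum-overlap fraction of the gene's coding span |

Open design points resolved here, as this package's own choices:

* **MAF aggregation** is the maximum across all reporting populations —
  the conservative rule when no canonical single resource is mandated;
  it is antitone in every frequency, so it can only remove variants
  relative to any single-resource rule.
* **Consensus quorum.** No standard exists for "how many of ten
  predictors"; strict majority of non-missing calls with a five-call
  floor is the default and both knobs are exposed.
* **Intolerance cutoffs** (Z > 0; percentile ≤ 25, low = intolerant) are
  acknowledged as arbitrary and therefore annotation-only by default:
  established predisposition genes are not uniformly missense-intolerant,
  so a hard cut would be a silent sensitivity hazard.
* **Conservation coverage.** Requiring all *present* scores to pass
  (rather than all three to be present) keeps genome- and exome-annotated
  families comparable when annotation coverage differs.
* **Conservation applies to missense only**; LoF variants are damaging
  through truncation/splice disruption, not site conservation.
* **Segregation edge cases.** A family with no sequenced affected member
  makes segregation uninterpretable and raises; if missing genotypes
  exclude every affected member, the variant fails rather than passing
  vacuously. Members of unknown affection are counted on neither side.
  Missing genotypes exclude the individual by default because sequencing
  dropout should not discard true candidates.
* **Dominant model only.** Carrier = het or hom-alt; recessive and
  compound-het models are out of scope for this cascade.
* **Candidate-gene counting** is the distinct gene symbols across the
  three tracks. Published cohort write-ups sometimes print two nearby
  totals for such counts depending on manual exclusions; the report
  emits the raw distinct count and leaves exclusions to the user's gene
  lists.

## Coordinates and formats

Internal coordinates are 1-based inclusive (the convention used when
intervals such as `chr4:15936942-16178663` are printed); BED I/O
converts at the boundary, and the conversion is a bijection on integer
intervals. The flat TSV dialect is the canonical lossless representation:
floats are written with `repr` (shortest round-trip rendering), so
write → read → write is byte-identical. VCF I/O (via pysam/htslib)
preserves structure exactly but numerics only to the format's text
precision (~6 significant digits). Predictor labels arrive in each
tool's native vocabulary ("D"/"T", "probably_damaging", …) and are
normalized to {deleterious, tolerated} through a shipped, overridable
mapping table; unknown consequence strings demote to `other` with a
logged count, and no input row is ever silently dropped.

## The synthetic cohort

The generator emulates the *statistical* structure the cascade assumes,
at desk scale: 21 families by default, each a 2–3 generation pedigree
with an affected carrier founder, 2–4 sequenced affected and 0–2
sequenced unaffected members. Affection equals latent-allele carrier
status (full penetrance), so planted variants — transmitted by seeded
Mendelian gene dropping — co-segregate exactly.

Background marginals (stipulated, with the analytic null in mind):

* CADD phred = −10·log₁₀(U), U uniform on (0, 1] — the phred rank
  definition, so exactly 1% of background mass clears the 20 gate;
* allele frequency log-uniform on [10⁻⁵, 0.05], reported identically in
  two resources, giving P(pass rarity) = ln 100 / ln 5000 ≈ 0.541;
* GERP ~ U(−3, 6), PhastCons ~ U(0, 1), PhyloP ~ U(−5, 9);
* each predictor call present with p = 0.9 and deleterious with p = 0.2
  (background) vs 0.9 (planted, resampled to guarantee a strict
  majority);
* background genotypes: carrier with p = 0.25 per sequenced member,
  independent of affection — the exchangeable null the segregation gate
  must reject;
* consequence mix 55% missense / 30% other / 7% splice / 4% frameshift /
  4% stopgain.

Failing-regime plants sample exactly one gate's evidence on the wrong
side of its threshold (for segregation, one genotype is flipped against
co-segregation), recorded per gate in the ground truth. The closed-form
survivor moments in `null_shared_gate_moments` let tests check that the
pipeline does not distort the null (observed background survivors within
3σ of the binomial prediction).

CNVs: seven planted segments whose carriers are exactly the sequenced
affected members, placed over a deterministic tiled gene model to cover
eleven distinct coding genes (including a worked-example chr4
duplication spanning FGFBP1/FGFBP2/PROM1/TAPT1); decoys are guaranteed
non-segregating by forcing one affected non-carrier, which fails every
policy that requires all affected to carry.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: linkage disequilibrium and
haplotype structure, within-family Mendelian consistency of *background*
genotypes, reduced penetrance and phenocopies, correlated annotation
scores (real conservation and predictor scores are strongly correlated;
here they are independent, which makes the background consensus gate
easier than in practice), multi-allelic sites, and realistic CNV size or
frequency distributions. Recovery results on synthetic cohorts validate
the plumbing and the gate logic, not field performance.

## Problem sizes and numerics

Default tests and the acceptance script run one 21-family × 1000
background-variant cohort (~21k records, a couple of seconds end to
end), 10⁴-point phred rankings, 10⁴-child transmission checks, and
exhaustive 3⁵ (and 4³ with missing states) segregation enumerations —
sizes chosen so the whole suite exercises every code path in seconds
while keeping binomial checks statistically meaningful. All randomness
flows through `numpy.random.default_rng(seed)`; identical (spec, seed)
reproduces cohorts and written outputs byte-for-byte (report floats are
rendered at fixed precision). Ties and degenerate inputs: zero available
predictor calls report fraction 0.0 and fail; empty inputs yield empty
outputs; zero-length BED intervals and inverted intervals are format
errors; genes with explicit coding-region features are queried on those,
gene-span-only records fall back to the whole span.

## Known limitations

* The ten-predictor consensus treats calls as exchangeable votes; no
  per-tool weighting or meta-score.
* No in-cohort allele-frequency estimation, kinship verification, or
  linkage statistics (LOD scores) — segregation is a per-family
  predicate, evaluated independently when a variant appears in several
  families.
* CNV carrier status is binary; dosage, breakpoints and reciprocal
  overlap criteria are out of scope.
* Functional curation (gene-function databases, literature, driver-gene
  catalogues) is manual by nature; only a gene-list intersection utility
  is provided.
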