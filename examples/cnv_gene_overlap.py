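"""Which coding genes does a segregating CNV affect?

Uses the chr4:15936942-16178663 duplication against the bundled fixture
gene model: the segment's coding-region overlap is exactly the two FGF
binding-protein genes, PROM1 and TAPT1.
"""

from famseq import genes_overlapping
from famseq.synthetic_cohort import cnv_worked_example

segment, gene_models = cnv_worked_example()
genes = genes_overlapping(segment, gene_models)

print(f"{segment.cnv_type} {segment.chrom}:{segment.start}-{segment.end}")
print(f"coding genes overlapped ({len(genes)}): {', '.join(genes)}")
# FGFBP1, FGFBP2, PROM1, TAPT1 — every gene with >= 1 coding base inside
# the duplicated interval, in genomic order.
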