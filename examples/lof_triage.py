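"""Triage a loss-of-function candidate panel.

Frameshift/stopgain records are gated on the MutPred-LOF score (> 0.50);
splice-site records on the splicing-motif yes/no flag. Both the full
list and the thresholded sublist matter: the score gate is a ranking
aid, not an exclusion.
"""

from famseq import triage_lof
from famseq.lof_track import class_counts
from famseq.synthetic_cohort import lof_benchmark_panel

panel = lof_benchmark_panel()
triaged = triage_lof(panel)

print(f"full LoF list: {sum(class_counts(triaged).values())} records "
      f"{class_counts(triaged)}")
passed = [c for c in triaged if c.gate_status == "pass"]
print(f"score/flag gate keeps: {class_counts(passed)}")
# 2 frameshift + 6 stopgain clear the MutPred-LOF 0.50 threshold and 5 of
# 8 splice-site records are predicted to alter a splicing motif.
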