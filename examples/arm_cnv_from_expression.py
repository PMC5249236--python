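"""Detecting an arm-level duplication from RNA-seq alone.

Plants a chromosome-1 q-arm duplication (DNA factor 2) in a single MK
technical replicate, then contrasts the two replicates' expression:
transcripts on the duplicated arm shift up, but dosage attenuation
keeps the mean log2 fold change well below 1 (= log2 of 2).
"""

import mkintegrity as mk
from mkintegrity.de import iqr_filter
from mkintegrity.expr_cnv import arm_contrast, replicate_fold_change

tx = mk.simulate_transcript_annotation(2000, seed=8)
truth = mk.make_expression_truth(
    tx, arm_duplication=("P001", "A", "MK", "1", "q", 2.0), seed=8
)
study, _ = mk.simulate_expression_study(14, truth, transcripts=tx,
                                        noise_sd=0.5, seed=9)

retained = iqr_filter(study)
fc = replicate_fold_change(study, "MP001A", "MP001B", retained)
res = arm_contrast(fc, mk.default_armmap(), chrom="1", target_arm="q",
                   n_perm=9999, seed=10)
print(f"chr1 q-arm (duplicated in replicate A): mean log2 FC = "
      f"{res.target_mean:+.3f} over {res.target_n} transcripts")
print(f"chr1 p-arm (reference):                mean log2 FC = "
      f"{res.reference_mean:+.3f} over {res.reference_n} transcripts")
print(f"label-permutation p = {res.p:.4f} (floor 1/10000 at full separation)")
print("the q-arm mean sits well below 1: expression under-responds to the")
print("doubled DNA dosage, as real arm duplications do")
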