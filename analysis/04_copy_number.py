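"""Relative copy number from the simulated qPCR Ct matrix.

Runs the two-way ANOVA normalization with diploid-median anchoring,
averages assays per gene, calls amplifications at >= 4 copies, and
checks sensitivity/false-positive rate against the planted truth.
"""

import numpy as np

from _common import load_cohort, outdir
from bclandscape import io
from bclandscape.cna import anova_normalize, call_amplification, to_copy_number

cohort, qc, expr = load_cohort()
out = outdir()

signals = anova_normalize(cohort.ct)
cn = to_copy_number(signals, cohort.ct.assay_map)
amp = call_amplification(cn, threshold=4.0)
io.write_tsv(cn.cn.round(3), out / "04_copy_number.tsv")

truth_amp = cohort.copy_number >= 4.0
tp = int((amp & truth_amp).to_numpy().sum())
fn = int((~amp & truth_amp).to_numpy().sum())
fp = int((amp & ~truth_amp).to_numpy().sum())
tn = int((~amp & ~truth_amp).to_numpy().sum())

print(f"Ct matrix: {cohort.ct.ct.shape[0]} samples x {cohort.ct.ct.shape[1]} assays "
      f"({len(cn.cn.columns)} genes, {int(cn.assay_counts.iloc[0])} assays/gene)")
print(f"global median copy number after anchoring: "
      f"{float(np.median(cn.cn.to_numpy())):.6f}")
print(f"amplification calls at >=4 copies: sensitivity {tp / (tp + fn):.3f}, "
      f"false-positive rate {fp / (fp + tn):.5f} "
      f"({tp + fp} calls, {tp + fn} planted)")
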