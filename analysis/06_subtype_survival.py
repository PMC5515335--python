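"""Prognostic value of molecular subgroups with arms pooled.

Pools the two treatment arms and asks the cohort-level questions: do the
intrinsic subtypes separate DFS; is luminal B worse than luminal A within
the HR+ IHC group; is a PIK3CA mutation protective within HR+; and do the
arms differ within any subtype (they are simulated identically, so they
should not).
"""

import pandas as pd

from _common import load_cohort, outdir
from bclandscape import io, survival

cohort, qc, expr = load_cohort()
out = outdir()

ann = cohort.annotation
subtype = cohort.truth["subtype"]
hrpos = ann.index[ann["ihc_group"].str.startswith("HRpos")]

res = survival.pooled_arm_analysis(
    ann, subtype, contrasts=[("LumB", "LumA", hrpos)]
)
print(f"overall log-rank p across intrinsic subtypes: "
      f"{res['overall_logrank_p']:.2e}")

rows = []
fit = res["pairwise"]["LumB_vs_LumA"]
rows.append(("LumB_vs_LumA_within_HRpos", fit))
print(f"LumB vs LumA within HR+: HR {fit.hazard_ratio:.2f} "
      f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}), p={fit.p_value:.3f}")

mut = ann.loc[hrpos].copy()
fit_mut = survival.cox_fit(mut, "pik3ca", reference="wt")
rows.append(("PIK3CA_mut_vs_wt_within_HRpos", fit_mut))
print(f"PIK3CA mutant vs wild-type within HR+: HR {fit_mut.hazard_ratio:.2f} "
      f"(95% CI {fit_mut.ci95[0]:.2f}-{fit_mut.ci95[1]:.2f}), "
      f"p={fit_mut.p_value:.3f}")

for sub, f in res["arm_within_subtype"].items():
    if f is not None:
        rows.append((f"experimental_vs_control_within_{sub}", f))

table = pd.DataFrame(
    [
        {
            "contrast": name,
            "hazard_ratio": round(f.hazard_ratio, 3),
            "ci_low": round(f.ci95[0], 3),
            "ci_high": round(f.ci95[1], 3),
            "p": f.p_value,
            "n": f.n,
            "n_events": f.n_events,
        }
        for name, f in rows
    ]
).set_index("contrast")
io.write_tsv(table, out / "06_survival_contrasts.tsv")
print(f"wrote {len(table)} survival contrasts")
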