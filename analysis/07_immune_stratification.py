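"""Immune-high/low stratification and per-gene DFS association.

Within the TNBC and HR+ IHC subgroups separately: cluster on the immune
gene panel (Manhattan distance, Ward linkage), test immune-high vs
immune-low DFS with a treatment-adjusted Cox model, and fit per-gene Cox
models with BH correction across the panel.
"""

from _common import load_cohort, outdir
from bclandscape import immune, io, tnbc

cohort, qc, expr = load_cohort()
out = outdir()
ann = cohort.annotation.loc[expr.values.index]

for name, samples in {
    "TNBC": tnbc.select_tnbc(ann),
    "HRpos": ann.index[ann["ihc_group"].str.startswith("HRpos")],
}.items():
    strat = immune.immune_cluster(
        expr.values.loc[samples], cohort.panel.immune, subgroup=name
    )
    fit = immune.stratum_survival(strat, ann.loc[samples])
    n_high = int((strat.strata == immune.IMMUNE_HIGH).sum())
    print(f"[{name}] {n_high}/{len(samples)} immune-high; "
          f"immune-high vs low DFS: HR {fit.hazard_ratio:.2f} "
          f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}), p={fit.p_value:.3f}")

    table = immune.per_gene_survival(
        expr.values.loc[samples], ann.loc[samples], cohort.panel.immune
    )
    sig = table[table["q"] < 0.05]
    print(f"[{name}] {len(sig)}/{len(table)} immune genes associated with DFS "
          f"at BH q < 0.05")
    io.write_tsv(table.round(4), out / f"07_immune_genes_{name}.tsv")
    io.write_tsv(
        strat.strata.to_frame("stratum"), out / f"07_immune_strata_{name}.tsv"
    )
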