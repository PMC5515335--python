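"""Simulate the synthetic study cohort and summarize its composition.

Writes the generator configuration and a cohort-composition table
(intrinsic subtype counts, IHC groups, PIK3CA prevalence by subtype,
immune strata, DFS event rate) under results/.
"""

import pandas as pd

from _common import load_cohort, outdir, study_config
from bclandscape import io

cohort, qc, expr = load_cohort()
out = outdir()

io.write_config(study_config(), out / "01_simulation_config.yaml")

truth, ann = cohort.truth, cohort.annotation
rows = []
for sub, n in truth["subtype"].value_counts().items():
    mut = (ann.loc[truth["subtype"] == sub, "pik3ca"] == "mut").mean()
    rows.append({"subtype": sub, "n": n, "fraction": n / len(truth),
                 "pik3ca_mut_fraction": round(float(mut), 3)})
composition = pd.DataFrame(rows).set_index("subtype")
io.write_tsv(composition, out / "01_cohort_composition.tsv")

ihc = ann["ihc_group"].value_counts().rename("n").to_frame()
io.write_tsv(ihc, out / "01_ihc_groups.tsv")

print(f"simulated {len(truth)} tumors on {cohort.config.n_genes} genes "
      f"(+{cohort.config.n_housekeeping} housekeeping, "
      f"{cohort.config.n_negative_controls} negative controls)")
print(composition)
print(f"DFS events: {int(ann['dfs_event'].sum())} "
      f"({ann['dfs_event'].mean():.1%} of samples)")
print(f"immune-high fraction: {(truth['immune_stratum'] == 'immune-high').mean():.2f}")
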