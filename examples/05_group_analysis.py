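"""Full synthetic study: 23 subjects, age-adjusted group contrasts, FDR.

Generates the default cohort (12 HD gene-expanded, 11 controls, with the
study's age imbalance), runs physiology extraction, BOLD preprocessing,
Hilbert coupling and regional Fisher-z averaging for every subject, fits
z ~ group + age per region and reports the affected-region detections.
"""

import numpy as np

from cvrpipe import detection_rates, run_synthetic_study

study, cohort, affected = run_synthetic_study(seed=0)
table = study.group_result.table
sens, false = detection_rates(study, affected)

aff_names = sorted({f"region_{i + 1:03d}" for i in affected}
                   & set(table.index))
print(f"regions modelled             : {table.shape[0]}")
print(f"true affected regions        : {len(aff_names)}")
print(f"sensitivity at FDR < 0.05    : {100 * sens:.0f}%")
print(f"false flags (unaffected)     : {100 * false:.1f}%")
print(f"mean HD-control z difference : "
      f"{table.loc[aff_names, 'diff_est'].mean():.3f} (true -0.25)")
print()
cols = ["control_est", "hd_est", "diff_est", "p", "p_fdr"]
print(table.loc[aff_names[:5], cols].round(3).to_string())
# Each row mirrors the study's regional table: group estimates at age 50
# with the HD-minus-control difference, its unadjusted p and FDR-adjusted p.
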