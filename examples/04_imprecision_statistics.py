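"""Fit the measurement error model to repeated measurements.

Long-format table: subject, eye (some subjects contribute both eyes, which
are correlated), scan replicate (1/2), parameter, value.  The model
decomposes variance into subject, eye-within-subject and replicate error;
the imprecision SD is the replicate-error SD, and relative imprecision is
imprecision over the grand mean, in percent.
"""

import numpy as np
import pandas as pd

from lcmicro import compare_group_imprecision, fit_measurement_error_model

rng = np.random.default_rng(0)
rows = []
for group, resid_sd, n_subj in (("healthy", 0.9, 16), ("glaucoma", 0.3, 16)):
    for s in range(n_subj):
        subject = rng.normal(0, 2.0)
        for eye in (["OD", "OS"] if s % 3 == 0 else ["OD"]):
            eye_eff = rng.normal(0, 1.0)
            for rep in (1, 2):
                rows.append({
                    "subject_id": f"{group[:1]}{s:02d}", "eye_id": eye,
                    "group": group, "replicate": rep,
                    "parameter": "pore_diameter_mean",
                    "value": 24.2 + subject + eye_eff + rng.normal(0, resid_sd),
                })
table = pd.DataFrame(rows)

estimates = {}
for group in ("healthy", "glaucoma"):
    est = fit_measurement_error_model(table[table.group == group], "pore_diameter_mean")
    estimates[group] = est
    print(f"{group:<9} mean {est.mean_value:5.1f} um | imprecision SD "
          f"{est.imprecision_sd:.2f} um | relative {est.relative_imprecision:.1f}% "
          f"({est.n_eyes} eyes, {est.n_subjects} subjects)")

cmp = compare_group_imprecision(estimates["healthy"], estimates["glaucoma"], seed=1)
print(f"healthy/glaucoma imprecision variance ratio {cmp.variance_ratio:.1f} "
      f"(95% bootstrap CI {cmp.ci_low:.1f}-{cmp.ci_high:.1f})")
# The simulated healthy group has three times the residual SD (9x the
# variance); the CI excluding 1 flags the difference as significant.
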