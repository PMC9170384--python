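"""Diagnostic accuracy of TGFBR2 H-score cut points.

A sample is called HCC when its score falls strictly below the threshold.
Each cell shows the metric with its untruncated 95% Wald interval; as the
threshold rises, sensitivity grows and specificity falls.
"""

from ihcdx.diagnostics import sweep_table, threshold_sweep
from ihcdx.synthetic import default_cohort_config, generate_cohort

cohort = generate_cohort(default_cohort_config(seed=2))
sub = cohort[cohort["marker"] == "TGFBR2"]

results = threshold_sweep(
    sub["region"].to_numpy(),
    sub["h_score"].to_numpy(),
    thresholds=[115, 120, 125, 130, 135, 140, 145],
)
print(sweep_table(results).to_string())
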