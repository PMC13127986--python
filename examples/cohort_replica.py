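"""A small synthetic two-group cohort through the full analysis chain.

The treated group ("MK") gets its theta-high-gamma coupling quartered and
its low-gamma oscillation power doubled in the post-injection epoch; the
pipeline cleans both epochs per animal, computes baseline-normalised band
powers and PLV (averaging the two electrodes), and applies the
normality-gated group statistics. The printed report shows the omnibus
test, route, and group means +/- SEM per metric.
"""

from neurocarousel import replica_cohort_spec, run_cohort

spec = replica_cohort_spec(seed=42, n_per_group=5, window_duration=30.0)
res = run_cohort(spec)
print(res.report)
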