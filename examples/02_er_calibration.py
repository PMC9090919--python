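"""Calibrating an ER-status cutoff from ESR1 expression.

A labelled reference cohort (pathology ER status with 4.5% label noise) is
scanned over cutoffs in 0.1 steps between the target cohort's quartiles; the
cutoff with the best concordance to pathology then predicts ER status in the
unlabelled target cohort.
"""

from mutexome import SynthConfig, calibrate_er_cutoff, predict_er_status
from mutexome.synth import gen_er_cohort

ref_values, ref_labels = gen_er_cohort(SynthConfig(seed=1), 1000)
target_values, _ = gen_er_cohort(SynthConfig(seed=2), 500)

cal = calibrate_er_cutoff(ref_values, ref_labels, target_values)
print(f"grid: {cal.cutoff_grid[0]:.1f} .. {cal.cutoff_grid[-1]:.1f} (step 0.1)")
print(f"chosen cutoff {cal.chosen_cutoff:.1f} at concordance {cal.concordance:.3f}")
# With 4.5% label noise the best achievable concordance is ~0.955, reached
# at the planted cutoff of 5.6 log2(CPM+1).

status = predict_er_status(target_values, cal.chosen_cutoff)
print(f"target cohort: {(status == 'pos').sum()} ER+ of {len(status)} samples")
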