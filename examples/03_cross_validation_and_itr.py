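"""Leave-one-run-out validation, permutation chance level, and practical ITR.

The permutation test reassigns each trial's label to a non-attended object's
sequence and reruns the cross-validation, estimating the guessing level the
real accuracy must clear.
"""

from seqcca import (
    leave_one_run_out_cv,
    permutation_chance,
    segment_duration,
    wolpaw_itr,
)
from seqcca.simulate import eeg_preset, simulate_dataset

cfg = eeg_preset(n_subjects=1, n_runs=4, trials_per_run=12, seed=5)
ds = simulate_dataset(cfg)

report = leave_one_run_out_cv(ds.trials)
print(f"leave-one-run-out DA = {report.da:.3f} over {len(ds.trials)} trials")

perm = permutation_chance(ds.trials, n_perm=25, seed=5)
print(f"permutation guessing level = {perm['mean']:.3f} "
      f"(95% interval {perm['ci95'][0]:.3f}..{perm['ci95'][1]:.3f}; "
      "theoretical chance 1/12 = 0.083)")

trial_s = segment_duration(ds.trials[0].schedule, 0.8)
itr = wolpaw_itr(report.da, 12, trial_s, overhead_seconds=2.5)
print(f"practical ITR at DA {report.da:.3f}: {itr:.1f} bit/min "
      f"({trial_s:.2f} s stimulation + 2.5 s overhead per selection)")
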