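"""Cross-subject transfer: shared vs subject-specific sensor patterns.

Decodes each synthetic subject with a model trained only on the *other*
subjects.  When the cohort shares the evoked topography, transfer works;
when each subject has an unrelated topography, transfer collapses while
within-subject decoding stays high.
"""

import numpy as np

from seqcca import leave_one_run_out_cv, leave_one_subject_out
from seqcca.simulate import eeg_preset, simulate_dataset

base = dict(n_subjects=4, n_runs=2, trials_per_run=12, n_channels=16, snr=0.5)

for label, cfg in [
    ("shared topography",
     eeg_preset(**base, topography_mode="focal", subject_variability=0.1, seed=43)),
    ("subject-specific topography",
     eeg_preset(**base, topography_mode="random", seed=44)),
]:
    ds = simulate_dataset(cfg)
    by = ds.by_subject()
    transfer = leave_one_subject_out(by)
    within = np.mean([leave_one_run_out_cv(trs).da for trs in by.values()])
    print(f"{label}:")
    print(f"  within-subject cross-validated DA = {within:.3f}")
    print(f"  leave-one-subject-out transfer DA = {transfer.da:.3f}")
print("(chance = 1/12 = 0.083; the gap between the two cohorts is the "
      "mechanistic signature of non-transferable sensor patterns)")
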