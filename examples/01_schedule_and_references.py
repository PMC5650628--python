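"""Flash schedules and impulse reference functions.

Generates the default trial design (12 objects, 5 flashes each, SOA 1/6 s,
same-object gap >= 500 ms), then builds the binary reference matrix of one
object and expands a toy template through it.
"""

import numpy as np

from seqcca import (
    build_reference_set,
    expand_template,
    generate_schedule,
    onsets_to_samples,
    segment_duration,
)

sched = generate_schedule(seed=1)
print(f"flashes: {sched.n_flashes} (12 objects x 5 repetitions)")
print(f"segment duration: {segment_duration(sched, 0.8):.4f} s "
      "(last onset + 0.8 s post-window)")

gaps = [np.diff(sched.onset_times(e)).min() for e in range(12)]
print(f"smallest same-object onset gap: {min(gaps) * 1000:.1f} ms (constraint: >= 500)")

fs = 50.863  # decimated rate
n = round(segment_duration(sched, 0.8) * fs)
refs = build_reference_set(onsets_to_samples(sched, fs), n, d=41)
Y0 = refs[0]
print(f"reference matrix of object 0: shape {Y0.shape}, "
      f"ones per column: {int(Y0.sum(axis=0)[0])} (= number of flashes)")

hat = np.bartlett(41)
v = expand_template(Y0, hat)
print(f"surrogate time course v = Y @ s: {np.count_nonzero(v)} nonzero samples "
      "(five hat-shaped copies at the object's onsets)")
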