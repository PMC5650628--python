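# seqcca

Decoding covertly attended stimulus sequences from multichannel EEG/MEG with
jointly estimated spatial and matched filters.

## The problem

In a sequence-coded brain–computer interface, `m` on-screen objects (default
12) are each flashed `n_reps` times (default 5) in a pseudo-random order at a
fixed stimulus onset asynchrony (1/6 s), with two flashes of the same object
never closer than 500 ms. The user covertly attends one object; its flashes
act as oddballs and evoke a P300-like response. Because every object carries
a temporally unique onset sequence, identifying *which* sequence of evoked
responses is present in a single ~10.6 s trial identifies the attended
object — without any assumption about where on the scalp or in time the
response appears.

## The method

For each object `e`, the onset sequence is encoded as a binary impulse
matrix `Y_e ∈ {0,1}^{n×d}` whose column `j` has ones at samples `j + t` for
every onset `t` (window `d` = 41 samples = 0.8 s at 50.863 Hz). Multiplying
by a temporal weight vector `s ∈ R^d` lays a copy of `s` at every onset:
`v_e = Y_e s`.

Training trials are concatenated in time into a brain-signal matrix `X`
(samples × channels) and a reference matrix `Y` built from each trial's
*attended* sequence. Canonical correlation analysis then finds paired
weightings

    u_k = X w_k      (spatial filter → surrogate channel)
    v_k = Y s_k      (matched filter → surrogate time course)

maximising `ρ_k = corr(u_k, v_k)`. Components are retained while
`ρ_k ≥ 0.1` and a sequential Bartlett χ² test rejects, at α = 0.05, the
null that all remaining correlations are zero.

To decode a new trial, every object's candidate time courses `v_{k,e} =
Y_e s_k` are correlated with the surrogate channels `u_k = X w_k`; the
per-object score is the mean over components of `atanh(ρ_{k,e})`, and the
top-ranked object is the prediction. Before any training data exist, an
initial model (`w = 1` across channels, triangular "hat" template) decodes
the very first trial.

The package also implements the surrounding evaluation machinery:
leave-one-run-out cross-validation, a chronological online simulation with
the protocol's update schedule, leave-one-subject-out transfer learning, an
incrementally substituted foreign-trial pool, label-permutation chance
levels, stimulus truncation, channel-subset selection, difference waves,
matched-filter similarity statistics, and the Wolpaw information transfer
rate — plus a synthetic EEG/MEG cohort generator so the whole pipeline runs
without recorded data.

## Worked example

```sh
python examples/02_train_and_decode.py
```

prints (seeded, reproducible):

```
retained components K = 1, canonical correlations = [0.31]
first matched filter vs planted evoked template: r = 0.992
held-out run: DA = 0.833 (10/12 trials correct; chance would be 1/12 = 0.083)
example trial: true object 0, predicted 0, score margin 0.234
```

The synthetic subject's planted evoked waveform is recovered almost exactly
by the first matched filter (`r = 0.992`), and decoding the held-out run is
far above the 1/12 guessing level. `examples/03_cross_validation_and_itr.py`
adds the permutation chance level (≈ 0.083) and the practical information
transfer rate; `examples/04_transfer_learning.py` contrasts cross-subject
decoding between cohorts with shared vs subject-specific topographies.

A thin CLI wraps the same functions:

```sh
seqcca simulate --preset eeg --subjects 1 --runs 4 --seed 0 --out data.h5
seqcca train --data data.h5 --out model.h5
seqcca decode --model model.h5 --data data.h5 --out results.csv
seqcca evaluate --data data.h5 --scheme cv --out report
```

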