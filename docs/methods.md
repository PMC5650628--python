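# Methods

## Model and procedure

A trial is a matrix `X ∈ R^{n×c}` (samples × channels) recorded while `m`
objects flash in a constrained pseudo-random order: each object `n_reps`
times, consecutive flashes 1/6 s apart (SOA), same-object flashes at least
0.5 s apart (equivalently ≥ 3 flash slots, i.e. at least two other-object
flashes in between). The attended object's flashes are assumed to evoke a
stereotyped response; ignored flashes are assumed to evoke none beyond a
response common to *all* flashes.

Each object's sequence is encoded by impulse reference functions: a binary
matrix `Y_e ∈ {0,1}^{n×d}` with `y_e(i,j) = 1` iff `i = j + t` for an onset
sample `t` of object `e` (0-based; windows that would cross the end of the
trial are truncated rather than padded — this only arises when trials are
deliberately shortened). `Y_e s` is then the overlap-add of copies of the
temporal weight vector `s` at the object's onsets.

Training concatenates trials along time into `X` and `Y` (the attended
object's reference matrix per trial) and solves CCA for spatial filters
`w_k` and matched filters `s_k` maximising `ρ_k = corr(X w_k, Y s_k)`.
Decoding projects a trial to surrogate channels `u_k = X w_k`, builds
`v_{k,e} = Y_e s_k` for every candidate object, and scores each object by
the mean over retained components of `atanh(ρ_{k,e})`; the argmax is the
prediction, ties breaking deterministically toward the lowest object index.

## Numerical choices

- **CCA solver.** Whitened-covariance SVD: `ρ` are the singular values of
  `C_xx^{-1/2} C_xy C_yy^{-1/2}`. Each block covariance receives a ridge of
  `ε·trace/dim` (default `ε = 1e-8`, configurable) so that rank-deficient
  regimes — 245 channels with few training trials — remain solvable.
  Columns are centered once after concatenation. Channels are standardized
  for conditioning before the solve and the scaling is folded back into the
  returned `W`, so models apply to raw trials; this changes the retained
  correlations by well under 1e-6 on well-conditioned data.
- **Sign convention.** CCA components are sign-indeterminate; the sign is
  fixed so each matched filter's dominant deflection is positive, making
  filters comparable across fits and subjects.
- **Component retention.** Retain the leading components with `ρ_k ≥ 0.1`
  *and* a sequential Bartlett test `χ² = −(N−1−(c+d+1)/2) Σ_{j≥k}
  ln(1−ρ_j²)` with `(c−k+1)(d−k+1)` degrees of freedom significant at
  α = 0.05. The conjunction is the reading that matches the stated intent
  of discarding weak surrogate channels. `K = 0` is valid: the model is
  flagged degenerate and the decoder substitutes the initial model
  (all-ones spatial filter, triangular hat template peaking at the window
  center), which is also how the very first trial of a session is decoded.
- **atanh clamp.** Correlations are clamped to `1 − 1e-12` in magnitude
  before the transform; degenerate perfect correlations occur on toy
  inputs. A zero-variance surrogate time course contributes ρ = 0.
- **Filtering.** The anti-alias low-pass is a Hamming windowed-sinc FIR with
  cutoff at the output Nyquist frequency and transition band ≤ 0.2× the
  output Nyquist, applied forward–backward (zero phase — phase distortion
  would shift matched-filter latencies). 100 ms buffers at each end of the
  segment absorb the filter transients and are trimmed before decimation.
  Reference-sensor noise cancellation is an ordinary least-squares
  projection per trial (pseudo-inverse with a logged warning when the
  reference set is rank deficient); adaptive variants are out of scope.
- **Sample indexing.** 0-based throughout; seconds-to-samples conversions
  round half away from zero. The same-object gap is enforced in flash-slot
  units to avoid float comparisons.
- **Schedule generation.** Rejection sampling over uniform shuffles with a
  small retry cap, then randomized greedy placement (most-constrained
  object first) with backtracking and a span-feasibility prune. For the
  default 12×5 gap-3 design a uniform shuffle is almost never valid, so the
  greedy path does the bulk of the work. Infeasible constraints raise an
  error; the constraint is never silently relaxed. Everything is
  deterministic given a seed.

## Evaluation machinery

- Leave-one-run-out cross-validation pools fold results; it is invariant to
  trial order and deterministic.
- The online simulation decodes trial 1 with the initial model and refits
  from all past trials after every trial during the first two runs, then at
  run boundaries — mirroring closed-loop operation.
- Leave-one-subject-out trains one model per held-out subject on all other
  subjects' trials.
- The pooled-transfer curve starts from the `n_pool` foreign trials whose
  own target sequences score highest under the donor-group model (the
  interpretation adopted for "highest canonical correlation" as a trial
  selection rule), then substitutes individual trials one at a time; the
  lowest-scoring pool trials are dropped first (the substitution order is
  not otherwise specified; this choice discards the least reliable foreign
  data earliest). The final step trains on purely individual data.
- The permutation test reassigns each trial's label uniformly to one of the
  `m−1` non-attended sequences (with replacement across trials) and reruns
  the cross-validation; the mean of the resulting DA distribution is the
  guessing level, with a 95% percentile interval.
- Practical ITR: `B = log2 N + P log2 P + (1−P) log2((1−P)/(N−1))` bits per
  selection, converted to bit/min over stimulation time plus a 2.5 s
  feedback/preparation overhead. Limits at `P ∈ {0, 1}` are handled
  exactly.
- Stimulus truncation keeps the first `reps_kept × m` flash slots and cuts
  the segment at the last kept onset + 0.8 s. Realised per-object counts
  may then be unequal, exactly as when an ongoing trial is stopped early.

Group inferential statistics (Wilcoxon, ANOVA) are deliberately not
implemented; they are routine and orthogonal to the decoding method.

## Synthetic cohorts

The generator emulates the statistical structure the decoder assumes, on
the raw 508.63 Hz grid, and pushes every trial through the real
preprocessing path (segment + buffers → zero-phase FIR → trim → decimate by
10 → 50.863 Hz, 541-sample trials, `d = 41`):

- **Evoked response**: Gaussian deflection, peak latency 0.40 s (EEG-like
  preset, 29 channels) or 0.34 s (MEG-like preset, 245 channels), width
  0.06 s, placed at every attended-object onset on a focal unit-norm
  topography.
- **Stimulus-locked common activity**: an identical short response placed
  at *every* flash onset on a broad topography; superimposed at the 1/6 s
  SOA this produces the ~6 Hz oscillation that appears in both attended and
  ignored epoch averages and cancels in their difference.
- **Noise**: 16 spatially smooth pink-noise sources plus white sensor
  noise (default per-channel SDs 0.7 each). The smooth sources give the
  spatial covariance a dominant low-rank structure, which is what makes
  ridge regularization necessary at 245 channels.
- **`snr`** scales the evoked waveform so that, in the virtual channel
  obtained by projecting onto the subject's topography, the evoked standard
  deviation is `snr` times the realized noise standard deviation. The
  default `snr = 0.2` was chosen once so that leave-one-run-out accuracy on
  a default single-subject cohort lands in the 0.85–1.0 band; `snr ≈ 0.5`
  behaves as an effectively high-SNR regime.
- **Between-subject structure**: `subject_variability` perturbs topography
  and latency around the shared pattern; `topography_mode="random"` gives
  every subject an unrelated smooth topography, the regime in which
  cross-subject transfer collapses while within-subject decoding is
  unaffected.
- Targets are balanced within runs (each object attended equally often per
  run); all randomness descends from a single seed via spawned seed
  sequences, so datasets are bit-identical across runs.

What the synthetic cohorts do *not* contain: eye blinks and other
artifacts, volume-conduction or lead-field physics, non-stationarities,
latency jitter across events, or EOG channels. Passing tests on this
generator therefore establishes the correctness and the statistical
behavior of the algorithms (recovery of planted templates and topographies,
chance-level calibration, monotonic trends in SNR/repetitions/channels, the
shared-vs-idiosyncratic transfer contrast) — not performance figures for
real recordings.

One subtlety of permutation calibration: when the permuted labels exclude
each trial's true object and the data contain exploitable signal, an
accurate decoder's agreement with the permuted labels is slightly *below*
1/m by construction. The chance-calibration check therefore runs on a
signal-free cohort, where the guessing symmetry is exact; separation of the
real accuracy from the permutation interval is checked on cohorts with
signal.

## Test and script problem sizes

The packaged checks use single-subject cohorts of 48–60 trials (29
channels), small 4-object designs for scheme-level tests, 100-permutation
chance runs on 8-channel cohorts, and 4-subject transfer cohorts at 16
channels — sizes chosen so each property is measured with comfortable
statistical margin while the whole suite stays lightweight. The acceptance
script touches only the schedule generator (1,000 default schedules).

## Known limitations

- The EDF reader treats one file as one trial segment and expects flash
  annotations (`flash:<object>`) or a JSON sidecar with the schedule; it
  does not segment multi-trial continuous recordings.
- Reference-sensor cancellation is plain least squares, not the adaptive
  original.
- No artifact rejection, dynamic stopping, or probabilistic score
  calibration.
- The online simulation replays recorded labels; it does not model the
  feedback/error-correction loop of a live session.
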