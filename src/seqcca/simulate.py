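"""Synthetic EEG/MEG-like trial generator.

Emulates the statistical structure the decoder assumes: a P300-like evoked
deflection at attended-stimulus latencies on a focal topography, a ~6 Hz
stimulus-locked oscillation common to *all* flashes (modelled as identical
visual responses superimposed at every flash onset, not a free-running
sinusoid), spatially correlated pink noise plus white sensor noise, and
between-subject variability of topography and latency.  Trials are generated
on the raw 508.63 Hz grid with 100 ms filter buffers and pushed through the
real preprocessing path, so simulated data exercise every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import TrialData, lowpass_decimate
from .schedule import (
    DEFAULT_MIN_GAP,
    DEFAULT_N_OBJECTS,
    DEFAULT_N_REPS,
    DEFAULT_SOA,
    StimulusSchedule,
    generate_schedule,
    onsets_to_samples,
    round_half_up,
    segment_duration,
)

__all__ = [
    "SimulationConfig",
    "SubjectParams",
    "SimulatedDataset",
    "eeg_preset",
    "meg_preset",
    "make_subject",
    "simulate_trial",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``snr`` scales the evoked response relative to the per-channel noise
    standard deviation (measured in the topography-projected channel on the
    raw grid).  ``subject_variability`` disperses per-subject topography and
    peak latency; ``topography_mode="random"`` draws an independent smooth
    topography per subject (the regime where cross-subject transfer fails).
    """

    n_channels: int = 29
    fs_raw: float = 508.63
    unit_scale: float = 1.0
    # stimulus design
    n_objects: int = DEFAULT_N_OBJECTS
    n_reps: int = DEFAULT_N_REPS
    soa: float = DEFAULT_SOA
    min_gap: float = DEFAULT_MIN_GAP
    post_window: float = 0.8
    buffer: float = 0.1
    decim_factor: int = 10
    # evoked response
    template_latency: float = 0.40  # s after stimulus onset (P300-like)
    template_width: float = 0.06  # Gaussian sigma, s
    snr: float = 0.2
    # stimulus-locked common response (~6 Hz once superimposed at every flash)
    ssvep_amp: float = 0.5
    ssvep_latency: float = 0.10
    ssvep_width: float = 0.03
    # noise
    noise_white: float = 0.7  # per-channel std of white sensor noise
    noise_pink: float = 0.7  # per-channel std of spatially correlated pink noise
    n_pink_sources: int = 16
    # cohort structure
    topography_mode: str = "focal"  # "focal" | "random"
    subject_variability: float = 0.3
    n_subjects: int = 1
    n_runs: int = 4
    trials_per_run: int = 12
    seed: int = 0


def eeg_preset(**overrides) -> SimulationConfig:
    """29-channel EEG-like array, P300 peak near 400 ms."""
    cfg = SimulationConfig(
        n_channels=29, template_latency=0.40, unit_scale=1e-6, topography_mode="focal"
    )
    return replace(cfg, **overrides)


def meg_preset(**overrides) -> SimulationConfig:
    """245-channel MEG-like array, earlier peak near 340 ms, focal bilateral pattern."""
    cfg = SimulationConfig(
        n_channels=245,
        template_latency=0.34,
        unit_scale=1e-13,
        topography_mode="focal",
    )
    return replace(cfg, **overrides)


@dataclass
class SubjectParams:
    """Planted forward-model parameters for one synthetic subject."""

    topography: np.ndarray  # (c,), unit norm
    template: np.ndarray  # evoked waveform on the raw grid over the post-window
    latency: float
    ssvep_topography: np.ndarray
    seed_entropy: int


@dataclass
class SimulatedDataset:
    """Cohort of labeled trials plus the ground-truth subject parameters."""

    trials: list[TrialData]
    subjects: dict[int | str, SubjectParams]
    config: SimulationConfig

    def by_subject(self) -> dict:
        out: dict = {}
        for tr in self.trials:
            out.setdefault(tr.subject_id, []).append(tr)
        return out


def _smooth_random(c: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm smooth random channel pattern (white draw, Gaussian-blurred)."""
    from scipy.ndimage import gaussian_filter1d

    raw = rng.standard_normal(c)
    sm = gaussian_filter1d(raw, sigma=max(c / 8.0, 0.5), mode="wrap")
    n = np.linalg.norm(sm)
    return sm / (n if n > 0 else 1.0)


def _focal_pattern(c: int) -> np.ndarray:
    """Deterministic focal bump over the channel axis (shared cohort pattern)."""
    i = np.arange(c)
    pat = np.exp(-0.5 * ((i - 0.45 * c) / (0.12 * c)) ** 2)
    return pat / np.linalg.norm(pat)


def _gauss_wave(
    fs: float, length_s: float, latency: float, width: float
) -> np.ndarray:
    t = np.arange(round_half_up(length_s * fs)) / fs
    return np.exp(-0.5 * ((t - latency) / width) ** 2)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    tc = np.fft.irfft(spec / np.sqrt(f), n=n)
    sd = tc.std()
    return tc / (sd if sd > 0 else 1.0)


def make_subject(config: SimulationConfig, subject_seed) -> SubjectParams:
    """Draw one subject's topography, evoked template, and latency.

    With ``subject_variability == 0`` every subject is identical.  In
    ``"random"`` topography mode subjects share nothing but the task
    structure, emulating non-transferable sensor patterns.
    """
    if isinstance(subject_seed, np.random.SeedSequence):
        ss = subject_seed
    else:
        ss = np.random.SeedSequence(subject_seed)
    rng = np.random.default_rng(ss)
    c = config.n_channels
    v = config.subject_variability
    if config.topography_mode == "random":
        topo = _smooth_random(c, rng)
    else:
        topo = _focal_pattern(c) + v * _smooth_random(c, rng)
        topo /= np.linalg.norm(topo)
    latency = float(
        np.clip(
            config.template_latency + v * 0.03 * rng.standard_normal(),
            0.15,
            config.post_window - 2 * config.template_width,
        )
    )
    template = _gauss_wave(
        config.fs_raw, config.post_window, latency, config.template_width
    )
    ssvep_topo = np.ones(c) / np.sqrt(c) + 0.1 * _smooth_random(c, rng)
    ssvep_topo /= np.linalg.norm(ssvep_topo)
    return SubjectParams(
        topography=topo,
        template=template,
        latency=latency,
        ssvep_topography=ssvep_topo,
        seed_entropy=int(ss.generate_state(1)[0]),
    )


def _overlap_add(
    n: int, onset_samples: np.ndarray, wave: np.ndarray
) -> np.ndarray:
    out = np.zeros(n)
    L = len(wave)
    for t in onset_samples:
        stop = min(t + L, n)
        out[t:stop] += wave[: stop - t]
    return out


def simulate_trial(
    subject: SubjectParams,
    schedule: StimulusSchedule,
    target: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    raw: bool = False,
) -> TrialData:
    """Forward-model one trial and (by default) run it through preprocessing.

    Raw-grid composition: evoked template at the target's onsets on the
    subject topography, common per-flash visual response at *every* onset on
    a broad topography, correlated pink noise, white noise.  The evoked
    amplitude is scaled so that, in the topography-projected channel, the
    evoked standard deviation is ``snr`` times the expected noise standard
    deviation.  With ``raw=True`` the 508.63 Hz segment (buffers included)
    is returned instead of the decimated trial.
    """
    if not 0 <= target < schedule.n_objects:
        raise ValueError("target out of range")
    fs = config.fs_raw
    dur = segment_duration(schedule, config.post_window)
    n = round_half_up((dur + 2 * config.buffer) * fs)
    off = round_half_up(config.buffer * fs)
    c = config.n_channels

    target_onsets = off + np.array(
        [round_half_up(t * fs) for t in schedule.onset_times(target)], dtype=int
    )
    all_onsets = off + np.array(
        [round_half_up(t * fs) for t in schedule.all_onset_times()], dtype=int
    )

    # noise first: its realized projection onto the subject topography sets
    # the evoked scale, so `snr` is an honest signal-to-noise ratio in the
    # virtual channel a perfect spatial filter would extract
    noise = np.zeros((n, c))
    proj_var = 0.0
    if config.noise_pink > 0:
        amp = config.noise_pink * np.sqrt(c / config.n_pink_sources)
        for _ in range(config.n_pink_sources):
            topo_s = _smooth_random(c, rng)
            noise += amp * np.outer(_pink_noise(n, rng), topo_s)
            proj_var += (amp * float(topo_s @ subject.topography)) ** 2
    if config.noise_white > 0:
        noise += rng.normal(0.0, config.noise_white, size=(n, c))
        proj_var += config.noise_white**2

    evoked_tc = _overlap_add(n, target_onsets, subject.template)
    noise_sd = np.sqrt(proj_var) or 1.0
    sd = evoked_tc.std()
    if sd > 0 and config.snr > 0:
        evoked_tc = evoked_tc * (config.snr * noise_sd / sd)
    else:
        evoked_tc = np.zeros(n)

    ssvep_wave = _gauss_wave(
        fs, 2 * config.ssvep_latency + 4 * config.ssvep_width,
        config.ssvep_latency, config.ssvep_width,
    )
    ssvep_tc = config.ssvep_amp * _overlap_add(n, all_onsets, ssvep_wave)

    X = np.outer(evoked_tc, subject.topography)
    X += np.outer(ssvep_tc, subject.ssvep_topography)
    X += noise
    X *= config.unit_scale

    trial = TrialData(
        X=X,
        fs=fs,
        schedule=schedule,
        channel_labels=[f"ch{i}" for i in range(c)],
        modalities=["sim"] * c,
        target=target,
        buffer=config.buffer,
    )
    if raw:
        return trial
    return lowpass_decimate(trial, config.decim_factor)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a labeled cohort: subjects x runs x trials.

    Targets are balanced within each run (each object attended equally
    often), so ``trials_per_run`` must be a multiple of ``n_objects``.
    Bit-identical for a given ``config.seed``.
    """
    if config.trials_per_run % config.n_objects != 0:
        raise ValueError(
            "trials_per_run must be a multiple of n_objects for balanced targets"
        )
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)
    trials: list[TrialData] = []
    subjects: dict = {}
    for sid, sseq in enumerate(subj_seqs):
        noise_seq, sched_seq, param_seq = sseq.spawn(3)
        subject = make_subject(config, param_seq)
        subjects[sid] = subject
        rng = np.random.default_rng(noise_seq)
        target_rng = np.random.default_rng(sched_seq)
        sched_seeds = sched_seq.generate_state(
            config.n_runs * config.trials_per_run + 1
        )[1:]
        k = 0
        for run in range(config.n_runs):
            targets = np.concatenate(
                [
                    target_rng.permutation(config.n_objects)
                    for _ in range(config.trials_per_run // config.n_objects)
                ]
            )
            for t in targets:
                schedule = generate_schedule(
                    config.n_objects,
                    config.n_reps,
                    config.soa,
                    config.min_gap,
                    seed=int(sched_seeds[k] % np.iinfo(np.int32).max),
                )
                k += 1
                trial = simulate_trial(subject, schedule, int(t), config, rng)
                trial.subject_id = sid
                trial.run_id = run
                trials.append(trial)
    return SimulatedDataset(trials=trials, subjects=subjects, config=config)
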