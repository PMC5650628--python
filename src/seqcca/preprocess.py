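"""Trial segmentation, anti-alias decimation, reference-noise cancellation, merging.

The nominal pipeline: extract a segment spanning first flash onset to 0.8 s
after the last (10.63 s for the default design) plus 100 ms filter buffers on
either side, cancel environmental noise by least-squares projection onto
reference sensors, low-pass at the target Nyquist frequency, trim the buffers,
and down-sample by a factor of 10 (508.63 Hz -> 50.863 Hz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .schedule import StimulusSchedule, round_half_up, segment_duration

__all__ = [
    "TrialData",
    "extract_segment",
    "lowpass_decimate",
    "regress_out_references",
    "merge_modalities",
]

log = logging.getLogger(__name__)

DEFAULT_POST_WINDOW = 0.8
DEFAULT_BUFFER = 0.1
DEFAULT_DECIM_FACTOR = 10


@dataclass
class TrialData:
    """One trial: samples x channels plus its flash schedule and metadata.

    ``buffer`` seconds of extra samples are present at each end of ``X``
    until :func:`lowpass_decimate` trims them; afterwards sample 0 is the
    first flash onset.  ``target`` is the attended object index or ``None``.
    """

    X: np.ndarray
    fs: float
    schedule: StimulusSchedule
    channel_labels: list[str] = field(default_factory=list)
    modalities: list[str] = field(default_factory=list)
    target: int | None = None
    run_id: int | str | None = None
    subject_id: int | str | None = None
    buffer: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x channels)")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.X.shape[1])]
        if not self.modalities:
            self.modalities = ["unknown"] * self.X.shape[1]
        if len(self.channel_labels) != self.X.shape[1]:
            raise ValueError("channel_labels inconsistent with X")
        if len(self.modalities) != self.X.shape[1]:
            raise ValueError("modalities inconsistent with X")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]


def extract_segment(
    continuous: np.ndarray,
    fs: float,
    schedule: StimulusSchedule,
    trial_start: float,
    post_window: float = DEFAULT_POST_WINDOW,
    buffer: float = DEFAULT_BUFFER,
    **meta,
) -> TrialData:
    """Cut one trial out of a continuous recording.

    ``trial_start`` is the time (s) of the trial's first flash onset within
    the recording.  The cut spans ``[trial_start - buffer,
    trial_start + (n_flashes-1)*soa + post_window + buffer]``; the buffers
    stay in place for filtering and are trimmed by :func:`lowpass_decimate`.
    """
    continuous = np.asarray(continuous, dtype=float)
    dur = segment_duration(schedule, post_window)
    i0 = round_half_up((trial_start - buffer) * fs) if trial_start - buffer >= 0 else -1
    i1 = i0 + round_half_up((dur + 2 * buffer) * fs)
    if i0 < 0 or i1 > continuous.shape[0]:
        raise ValueError(
            f"requested segment [{trial_start - buffer:.3f}, "
            f"{trial_start + dur + buffer:.3f}] s exceeds the recording"
        )
    return TrialData(
        X=continuous[i0:i1].copy(), fs=fs, schedule=schedule, buffer=buffer, **meta
    )


def _design_lowpass(fs: float, factor: int) -> np.ndarray:
    """Hamming windowed-sinc FIR, cutoff at the output Nyquist frequency.

    Transition band <= 0.2x the output Nyquist so stimulus-band content is
    untouched; applied forward-backward, so the effective attenuation is
    doubled and the phase response is zero (matched-filter latencies must
    not shift).
    """
    out_nyq = fs / (2 * factor)
    transition = 0.2 * out_nyq
    numtaps = int(math.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length
    return sps.firwin(numtaps, out_nyq, fs=fs, window="hamming")


def lowpass_decimate(trial: TrialData, factor: int = DEFAULT_DECIM_FACTOR) -> TrialData:
    """Anti-alias low-pass, trim filter buffers, down-sample by ``factor``.

    ``factor == 1`` is a passthrough that only trims the buffers.  After this
    step sample ``k`` sits at ``k / fs_out`` seconds from the first flash.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nb = round_half_up(trial.buffer * trial.fs)
    if factor == 1:
        X = trial.X[nb : trial.n_samples - nb if nb else trial.n_samples]
        return replace(trial, X=X.copy(), buffer=0.0)
    b = _design_lowpass(trial.fs, factor)
    if trial.n_samples <= 3 * len(b):
        raise ValueError(
            f"segment of {trial.n_samples} samples too short for a "
            f"{len(b)}-tap zero-phase filter"
        )
    Xf = sps.filtfilt(b, [1.0], trial.X, axis=0)
    if nb:
        Xf = Xf[nb : trial.n_samples - nb]
    Xd = Xf[::factor]
    return replace(trial, X=Xd.copy(), fs=trial.fs / factor, buffer=0.0)


def regress_out_references(
    trial: TrialData, reference_channels: np.ndarray
) -> TrialData:
    """Cancel environmental noise by least-squares projection onto reference sensors.

    Each data channel is replaced by its residual after regressing on the
    (time-aligned) reference channels; an empty reference set is a no-op.
    Rank-deficient references are handled by the pseudo-inverse with a
    logged warning.
    """
    R = np.asarray(reference_channels, dtype=float)
    if R.size == 0:
        return replace(trial, X=trial.X.copy())
    if R.ndim == 1:
        R = R[:, None]
    if R.shape[0] != trial.n_samples:
        raise ValueError("reference channels not time-aligned with the trial")
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        log.warning(
            "reference sensor set is rank deficient (%d < %d); using pseudo-inverse",
            rank,
            R.shape[1],
        )
    beta, *_ = np.linalg.lstsq(R, trial.X, rcond=None)
    return replace(trial, X=trial.X - R @ beta)


def merge_modalities(trial_a: TrialData, trial_b: TrialData) -> TrialData:
    """Concatenate the channels of two simultaneously recorded trials.

    Modality tags travel with the channels; no unit harmonisation is done
    because the downstream CCA is invariant to per-channel scaling.
    """
    if trial_b.n_channels == 0:
        return replace(trial_a, X=trial_a.X.copy())
    if not np.isclose(trial_a.fs, trial_b.fs):
        raise ValueError("sampling rates differ")
    if trial_a.n_samples != trial_b.n_samples:
        raise ValueError("sample counts differ")
    if trial_a.schedule.global_order != trial_b.schedule.global_order or not np.isclose(
        trial_a.schedule.soa, trial_b.schedule.soa
    ):
        raise ValueError("schedules differ between modalities")
    return TrialData(
        X=np.hstack([trial_a.X, trial_b.X]),
        fs=trial_a.fs,
        schedule=trial_a.schedule,
        channel_labels=list(trial_a.channel_labels) + list(trial_b.channel_labels),
        modalities=list(trial_a.modalities) + list(trial_b.modalities),
        target=trial_a.target,
        run_id=trial_a.run_id,
        subject_id=trial_a.subject_id,
        buffer=trial_a.buffer,
    )
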