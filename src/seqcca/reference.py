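"""Impulse reference functions for stimulus sequences.

Each object ``e`` gets a binary matrix ``Y_e`` of shape (n_samples, d): column
``j`` carries an impulse at row ``j + t`` for every onset sample ``t`` of that
object.  Multiplying ``Y_e`` by a length-``d`` matched filter ``s`` lays a copy
of ``s`` down at every onset (overlapping copies add), producing the surrogate
time course ``v_e = Y_e s`` that models the evoked response train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import StimulusSchedule, onsets_to_samples

__all__ = ["ReferenceSet", "build_reference_set", "expand_template", "references_for_trial"]


@dataclass
class ReferenceSet:
    """Binary impulse matrices ``Y_e``, one per object."""

    matrices: list[np.ndarray]  # each (n_samples, d)
    onset_samples: list[np.ndarray]
    n_samples: int
    d: int

    @property
    def n_objects(self) -> int:
        return len(self.matrices)

    def __getitem__(self, e: int) -> np.ndarray:
        return self.matrices[e]


def _impulse_matrix(onsets: np.ndarray, n_samples: int, d: int) -> np.ndarray:
    Y = np.zeros((n_samples, d))
    for t in onsets:
        j = np.arange(min(d, n_samples - t))
        Y[t + j, j] = 1.0
    return Y


def build_reference_set(
    onset_samples: list[np.ndarray], n_samples: int, d: int
) -> ReferenceSet:
    """Build one ``Y_e`` per object from per-object onset sample indices.

    Windows that would extend past the end of the trial are truncated (this
    only happens for truncated stimulation analyses; the nominal design's
    0.8 s post-window guarantees full windows).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    mats = []
    kept = []
    for e, onsets in enumerate(onset_samples):
        onsets = np.asarray(onsets, dtype=int)
        if onsets.size and (onsets.min() < 0 or onsets.max() >= n_samples):
            raise ValueError(
                f"object {e}: onset sample outside [0, {n_samples}) — "
                f"got range [{onsets.min()}, {onsets.max()}]"
            )
        mats.append(_impulse_matrix(onsets, n_samples, d))
        kept.append(onsets.copy())
    return ReferenceSet(matrices=mats, onset_samples=kept, n_samples=n_samples, d=d)


def expand_template(Y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Surrogate time course ``v = Y s``: overlap-added copies of ``s`` at each onset."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.shape[0] != Y.shape[1]:
        raise ValueError(f"template length {s.shape} does not match d={Y.shape[1]}")
    return Y @ s


def references_for_trial(
    schedule: StimulusSchedule, fs: float, n_samples: int, d: int
) -> ReferenceSet:
    """Reference set for a trial's schedule on its sample grid."""
    return build_reference_set(onsets_to_samples(schedule, fs), n_samples, d)
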