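"""Constrained pseudo-random flash schedules.

A trial of the covert-attention task highlights each of ``m`` on-screen
objects ``n_reps`` times at a fixed stimulus onset asynchrony (SOA), in a
pseudo-random order constrained so that two flashes of the *same* object are
never closer than a minimum gap (equivalently, are separated by a minimum
number of other-object flashes).  Every object is thereby tagged with a
temporally unique onset sequence, which is what the decoder discriminates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusSchedule",
    "ScheduleInfeasibleError",
    "generate_schedule",
    "onsets_to_samples",
    "segment_duration",
    "DEFAULT_N_OBJECTS",
    "DEFAULT_N_REPS",
    "DEFAULT_SOA",
    "DEFAULT_MIN_GAP",
]

DEFAULT_N_OBJECTS = 12
DEFAULT_N_REPS = 5
DEFAULT_SOA = 1.0 / 6.0  # 167 ms between consecutive flashes
DEFAULT_MIN_GAP = 0.5  # same-object onsets at least 500 ms apart


class ScheduleInfeasibleError(RuntimeError):
    """Raised when no flash ordering can satisfy the same-object gap constraint."""


def round_half_up(x: float) -> int:
    """Round a non-negative float half away from zero to an int."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class StimulusSchedule:
    """Per-trial flash schedule: one onset sequence per object.

    ``global_order[k]`` is the (0-based) object flashed in slot ``k``; slot
    ``k`` has onset ``k * soa`` seconds from the first flash.  ``n_reps`` is
    the design repetition count; after truncation the realised per-object
    counts may differ (see :func:`seqcca.evaluate.truncate_stimuli`).
    """

    n_objects: int
    n_reps: int
    soa: float
    min_same_object_gap: float
    global_order: tuple[int, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.soa <= 0:
            raise ValueError("soa must be positive")
        order = tuple(int(e) for e in self.global_order)
        object.__setattr__(self, "global_order", order)
        if any(e < 0 or e >= self.n_objects for e in order):
            raise ValueError("global_order entries must lie in [0, n_objects)")

    @property
    def n_flashes(self) -> int:
        return len(self.global_order)

    def slots_of(self, obj: int) -> np.ndarray:
        """Flash-slot indices of one object, ascending."""
        return np.flatnonzero(np.asarray(self.global_order) == obj)

    def onset_times(self, obj: int) -> np.ndarray:
        """Onset times (s from first flash) of one object's flashes."""
        return self.slots_of(obj) * self.soa

    def onsets_by_object(self) -> list[np.ndarray]:
        return [self.onset_times(e) for e in range(self.n_objects)]

    def all_onset_times(self) -> np.ndarray:
        """Onsets of every flash regardless of object."""
        return np.arange(self.n_flashes) * self.soa

    # --- JSON round trip -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_objects": self.n_objects,
                "n_reps": self.n_reps,
                "soa": self.soa,
                "min_same_object_gap": self.min_same_object_gap,
                "global_order": list(self.global_order),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSchedule":
        obj = json.loads(text)
        return cls(
            n_objects=obj["n_objects"],
            n_reps=obj["n_reps"],
            soa=obj["soa"],
            min_same_object_gap=obj["min_same_object_gap"],
            global_order=tuple(obj["global_order"]),
            seed=obj.get("seed"),
        )

    def truncated(self, n_slots: int) -> "StimulusSchedule":
        """Schedule restricted to its first ``n_slots`` flash slots."""
        if not 1 <= n_slots <= self.n_flashes:
            raise ValueError("n_slots out of range")
        return replace(self, global_order=self.global_order[:n_slots])


def _gap_slots(min_gap: float, soa: float) -> int:
    # Enforced in slot units to dodge float comparisons; 0.5 s at SOA 1/6 s
    # means >= 3 slots, i.e. at least two other-object flashes in between.
    return max(1, round_half_up(min_gap / soa))


def _order_ok(order: np.ndarray, n_objects: int, gap_slots: int) -> bool:
    for e in range(n_objects):
        slots = np.flatnonzero(order == e)
        if slots.size > 1 and np.diff(slots).min() < gap_slots:
            return False
    return True


def _backtrack_order(
    n_objects: int, n_reps: int, gap_slots: int, rng: np.random.Generator
) -> list[int] | None:
    """Greedy sequential placement, most-constrained object first, with
    backtracking.  A span prune discards branches where some object's
    remaining flashes can no longer fit at the required spacing."""
    total = n_objects * n_reps
    remaining = [n_reps] * n_objects
    last = [-gap_slots] * n_objects
    order: list[int] = []
    budget = 500_000

    def feasible(slot: int) -> bool:
        for e in range(n_objects):
            if remaining[e] == 0:
                continue
            first = max(slot, last[e] + gap_slots)
            if first + (remaining[e] - 1) * gap_slots > total - 1:
                return False
        return True

    def rec(slot: int) -> bool:
        nonlocal budget
        if slot == total:
            return True
        budget -= 1
        if budget < 0:
            raise ScheduleInfeasibleError(
                "backtracking budget exhausted while searching for a feasible order"
            )
        cands = [
            e
            for e in range(n_objects)
            if remaining[e] > 0 and slot - last[e] >= gap_slots
        ]
        # most urgent (highest remaining) first, random tie-break
        tie = {e: r for e, r in zip(cands, rng.random(len(cands)))}
        cands.sort(key=lambda e: (-remaining[e], tie[e]))
        for e in cands:
            order.append(e)
            remaining[e] -= 1
            prev = last[e]
            last[e] = slot
            if feasible(slot + 1) and rec(slot + 1):
                return True
            order.pop()
            remaining[e] += 1
            last[e] = prev
        return False

    return order if rec(0) else None


def generate_schedule(
    n_objects: int = DEFAULT_N_OBJECTS,
    n_reps: int = DEFAULT_N_REPS,
    soa: float = DEFAULT_SOA,
    min_gap: float = DEFAULT_MIN_GAP,
    seed: int | None = None,
    max_retries: int = 100,
) -> StimulusSchedule:
    """Draw a pseudo-random flash order satisfying the same-object gap.

    Rejection sampling over uniform shuffles with a retry cap; if the cap is
    reached, a randomized greedy placement with backtracking takes over
    (for the default 12x5 gap-3 design a uniform shuffle is rarely valid, so
    the cap is kept small and the greedy path does the bulk of the work).  A
    genuinely infeasible constraint raises :class:`ScheduleInfeasibleError`
    rather than being silently relaxed.  Deterministic for a given seed.
    """
    if n_objects < 1 or n_reps < 1:
        raise ValueError("n_objects and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    gap = _gap_slots(min_gap, soa)
    labels = np.repeat(np.arange(n_objects), n_reps)
    order = None
    for _ in range(max_retries):
        cand = rng.permutation(labels)
        if _order_ok(cand, n_objects, gap):
            order = cand.tolist()
            break
    if order is None:
        order = _backtrack_order(n_objects, n_reps, gap, rng)
    if order is None:
        raise ScheduleInfeasibleError(
            f"no ordering of {n_objects} objects x {n_reps} reps satisfies a "
            f"same-object gap of {gap} slots"
        )
    return StimulusSchedule(
        n_objects=n_objects,
        n_reps=n_reps,
        soa=soa,
        min_same_object_gap=min_gap,
        global_order=tuple(order),
        seed=seed,
    )


def onsets_to_samples(schedule: StimulusSchedule, fs: float) -> list[np.ndarray]:
    """Per-object onset sample indices (0-based) on a grid sampled at ``fs``.

    Indices are ``round(t * fs)`` with half-away-from-zero rounding, the
    first flash sitting at index 0.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    return [
        np.array([round_half_up(t * fs) for t in self_onsets], dtype=int)
        for self_onsets in schedule.onsets_by_object()
    ]


def segment_duration(schedule: StimulusSchedule, post_window: float = 0.8) -> float:
    """Trial segment length: first flash onset to ``post_window`` after the last.

    For the default 12-object, 5-repetition design at SOA 1/6 s this is
    59/6 + 0.8 ~= 10.63 s.
    """
    if schedule.n_flashes < 1:
        raise ValueError("schedule has no flashes")
    if post_window < 0:
        raise ValueError("post_window must be >= 0")
    return (schedule.n_flashes - 1) * schedule.soa + post_window
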