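"""Validation machinery: cross-validation, online simulation, transfer
learning, permutation chance levels, truncation/subset analyses, accuracy
and information-transfer-rate metrics, and signal-evaluation utilities."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cca import DEFAULT_D, FilterModel, initial_filter_model, train_filter_model
from .decode import DecodingResult, predict
from .preprocess import TrialData
from .schedule import onsets_to_samples, round_half_up

__all__ = [
    "EvaluationReport",
    "decoding_accuracy",
    "wolpaw_itr",
    "leave_one_run_out_cv",
    "online_simulation",
    "leave_one_subject_out",
    "select_pool",
    "pooled_transfer_curve",
    "permutation_chance",
    "truncate_stimuli",
    "component_similarity",
    "group_mean_similarity",
    "difference_wave",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class EvaluationReport:
    """Outcome of one evaluation scheme.

    ``da`` is the pooled decoding accuracy (proportion); curves are named
    sequences (e.g. cumulative DA per trial); ``per_subject`` maps subject id
    to its DA where the scheme involves several subjects.
    """

    scheme: str
    da: float
    per_subject: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    itr_bit_per_min: float | None = None
    permutation: dict | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None
    schema_version: int = SCHEMA_VERSION


def decoding_accuracy(results: list[DecodingResult]) -> float:
    """Fraction of trials whose attended object was correctly predicted."""
    if not results:
        raise ValueError("no decoding results")
    flags = [r.correct for r in results]
    if any(f is None for f in flags):
        raise ValueError("all results must carry a true label")
    return float(np.mean(flags))


def wolpaw_itr(
    P: float, N: int, trial_seconds: float, overhead_seconds: float = 0.0
) -> float:
    """Information transfer rate in bit/min.

    Bits per selection ``B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1))``
    with the 0*log0 limits handled, converted to a rate over
    ``trial_seconds + overhead_seconds`` ("practical" ITR when the overhead
    for feedback and preparation, e.g. 2.5 s, is included).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    B = math.log2(N)
    if P > 0.0:
        B += P * math.log2(P)
    if P < 1.0:
        B += (1.0 - P) * math.log2((1.0 - P) / (N - 1))
    return B * 60.0 / (trial_seconds + overhead_seconds)


# ---------------------------------------------------------------------------
# cross-validation and online schemes


def _group_by_run(trials: list[TrialData]) -> dict:
    runs: dict = {}
    for tr in trials:
        runs.setdefault(tr.run_id, []).append(tr)
    return runs


def leave_one_run_out_cv(
    trials: list[TrialData], d: int = DEFAULT_D, **fit_kwargs
) -> EvaluationReport:
    """Train on all runs but one, decode the held-out run; pool over folds."""
    runs = _group_by_run(trials)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least two runs")
    if any(len(v) == 0 for v in runs.values()):
        raise ValueError("empty run")
    results: list[DecodingResult] = []
    per_run: dict = {}
    for held in sorted(runs, key=str):
        train = [tr for rid, v in runs.items() if rid != held for tr in v]
        model = train_filter_model(train, d=d, **fit_kwargs)
        fold = [predict(tr, model) for tr in runs[held]]
        per_run[held] = decoding_accuracy(fold)
        results.extend(fold)
    return EvaluationReport(
        scheme="leave_one_run_out",
        da=decoding_accuracy(results),
        per_subject={},
        curves={"per_run_da": [per_run[k] for k in sorted(per_run, key=str)]},
        config={"d": d, **fit_kwargs},
    )


def online_simulation(
    trials: list[TrialData],
    d: int = DEFAULT_D,
    n_update_every_trial_runs: int = 2,
    **fit_kwargs,
) -> EvaluationReport:
    """Replay trials chronologically as in closed-loop operation.

    The first trial is decoded with the untrained initial model (all-ones
    spatial filter, hat-function template).  Afterwards the model is refit
    from all past trials — after every trial during the first
    ``n_update_every_trial_runs`` runs, then only at run boundaries.
    Returns the cumulative-DA curve and the per-trial correctness sequence.
    """
    if not trials:
        raise ValueError("no trials")
    run_order: list = []
    for tr in trials:
        if tr.run_id not in run_order:
            run_order.append(tr.run_id)
    model = initial_filter_model(trials[0].n_channels, d)
    results: list[DecodingResult] = []
    correct: list[bool] = []
    for i, tr in enumerate(trials):
        res = predict(tr, model)
        results.append(res)
        correct.append(bool(res.correct))
        run_idx = run_order.index(tr.run_id)
        last_of_run = i + 1 == len(trials) or trials[i + 1].run_id != tr.run_id
        if run_idx < n_update_every_trial_runs or last_of_run:
            model = train_filter_model(trials[: i + 1], d=d, **fit_kwargs)
    cum = np.cumsum(correct) / np.arange(1, len(correct) + 1)
    return EvaluationReport(
        scheme="online_simulation",
        da=decoding_accuracy(results),
        curves={"correct": [bool(b) for b in correct], "cumulative_da": cum.tolist()},
        config={"d": d, **fit_kwargs},
    )


def leave_one_subject_out(
    datasets: dict, d: int = DEFAULT_D, **fit_kwargs
) -> EvaluationReport:
    """Decode each subject with a model trained on every other subject's trials."""
    if len(datasets) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    c = next(iter(datasets.values()))[0].n_channels
    for sid, trs in datasets.items():
        if any(tr.n_channels != c for tr in trs):
            raise ValueError(f"subject {sid}: channel layout mismatch")
    per_subject: dict = {}
    results: list[DecodingResult] = []
    for sid in datasets:
        pool = [tr for other, trs in datasets.items() if other != sid for tr in trs]
        model = train_filter_model(pool, d=d, **fit_kwargs)
        fold = [predict(tr, model) for tr in datasets[sid]]
        per_subject[sid] = decoding_accuracy(fold)
        results.extend(fold)
    return EvaluationReport(
        scheme="leave_one_subject_out",
        da=decoding_accuracy(results),
        per_subject=per_subject,
        config={"d": d, **fit_kwargs},
    )


# ---------------------------------------------------------------------------
# transfer learning with a foreign-trial pool


def trial_score(trial: TrialData, model: FilterModel) -> float:
    """Score of a labeled trial's own target sequence under a model."""
    res = predict(trial, model)
    return float(res.scores[trial.target])


def select_pool(
    candidates: list[TrialData], model: FilterModel, n_pool: int = 100
) -> list[TrialData]:
    """Pick the ``n_pool`` foreign trials whose target sequences score highest
    under the donor-group model, i.e. the trials assumed most reliable for
    generalization.  Returned sorted by score, best first."""
    if n_pool < 1:
        raise ValueError("n_pool must be >= 1")
    scores = np.array([trial_score(tr, model) for tr in candidates])
    order = np.argsort(-scores, kind="stable")[:n_pool]
    return [candidates[i] for i in order]


def pooled_transfer_curve(
    individual: list[TrialData],
    pool: list[TrialData],
    d: int = DEFAULT_D,
    **fit_kwargs,
) -> EvaluationReport:
    """Warm-start decoding from a foreign pool, incrementally substituted.

    Step ``t`` decodes the individual's trial ``t`` with a model trained on
    the pool minus its ``t`` lowest-ranked trials plus the individual's first
    ``t`` trials; once ``t`` reaches the pool size the training set is purely
    individual data.  ``pool`` is assumed ordered best-first (see
    :func:`select_pool`).
    """
    if not pool:
        raise ValueError("empty pool")
    n_steps = min(len(individual), len(pool) + 1)
    correct: list[bool] = []
    n_pool_used: list[int] = []
    for t in range(n_steps):
        train = pool[: max(len(pool) - t, 0)] + individual[:t]
        model = train_filter_model(train, d=d, **fit_kwargs)
        res = predict(individual[t], model)
        correct.append(bool(res.correct))
        n_pool_used.append(max(len(pool) - t, 0))
    return EvaluationReport(
        scheme="pooled_transfer",
        da=float(np.mean(correct)),
        curves={"correct": correct, "n_pool_used": n_pool_used},
        config={"d": d, "n_pool": len(pool), **fit_kwargs},
    )


# ---------------------------------------------------------------------------
# permutation chance level


def permutation_chance(
    trials: list[TrialData],
    n_perm: int = 500,
    seed: int | None = None,
    d: int = DEFAULT_D,
    **fit_kwargs,
) -> dict:
    """Guessing-level distribution by relabeled cross-validation.

    Each permutation reassigns every trial's label to a uniformly drawn
    *other* object's sequence (attention to an object that was not actually
    attended) and reruns leave-one-run-out CV.  Returns the mean (the
    guessing level) and the 95% interval of the pooled-DA distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    m = trials[0].schedule.n_objects
    das = np.empty(n_perm)
    for p in range(n_perm):
        relabeled = []
        for tr in trials:
            others = [e for e in range(m) if e != tr.target]
            relabeled.append(replace(tr, target=int(rng.choice(others))))
        das[p] = leave_one_run_out_cv(relabeled, d=d, **fit_kwargs).da
    lo, hi = np.percentile(das, [2.5, 97.5])
    return {
        "mean": float(das.mean()),
        "ci95": (float(lo), float(hi)),
        "das": das,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# truncated stimulation


def truncate_stimuli(
    trial: TrialData, reps_kept: int, post_window: float = 0.8
) -> TrialData:
    """Shorten a trial to its first ``reps_kept * n_objects`` flash slots.

    The segment is cut at the last kept onset plus ``post_window``; with the
    pseudo-random order the realised per-object repetition counts may be
    unequal, exactly as when an ongoing trial is stopped early.
    ``reps_kept`` equal to the design count returns the trial unchanged.
    """
    sched = trial.schedule
    if reps_kept < 1:
        raise ValueError("reps_kept must be >= 1")
    if reps_kept > sched.n_reps:
        raise ValueError("reps_kept exceeds the design repetition count")
    if reps_kept == sched.n_reps:
        return trial
    n_slots = reps_kept * sched.n_objects
    new_sched = replace(
        sched, global_order=sched.global_order[:n_slots], n_reps=reps_kept
    )
    n_new = round_half_up(((n_slots - 1) * sched.soa + post_window) * trial.fs)
    n_new = min(n_new, trial.n_samples)
    return replace(trial, X=trial.X[:n_new].copy(), schedule=new_sched)


def truncate_dataset(
    trials: list[TrialData], reps_kept: int, post_window: float = 0.8
) -> list[TrialData]:
    return [truncate_stimuli(tr, reps_kept, post_window) for tr in trials]


# ---------------------------------------------------------------------------
# signal evaluation


def component_similarity(s_a: np.ndarray, s_b: np.ndarray) -> float:
    """Pearson correlation between two matched filters."""
    s_a = np.asarray(s_a, dtype=float).ravel()
    s_b = np.asarray(s_b, dtype=float).ravel()
    if s_a.shape != s_b.shape:
        raise ValueError("filters differ in length")
    if s_a.std() == 0 or s_b.std() == 0:
        raise ValueError("zero-variance filter")
    return float(np.corrcoef(s_a, s_b)[0, 1])


def group_mean_similarity(r_values) -> float:
    """Group-average correlation: atanh-transform, mean, back-transform."""
    r = np.clip(np.asarray(r_values, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.arctanh(r).mean()))


def difference_wave(
    trials: list[TrialData],
    model: FilterModel | None = None,
    channel: int | None = None,
    post_window: float = 0.8,
) -> dict:
    """Attended-minus-ignored average over post-stimulus epochs.

    Epochs span 0..``post_window`` s after every flash onset; events of the
    labeled target are "attended", all others "ignored".  Averaging runs on
    the first surrogate channel if ``model`` is given, on one sensor if
    ``channel`` is given, else on all channels.  Responses common to every
    flash (the ~6 Hz stimulus-locked oscillation) cancel in the difference.
    """
    if not trials:
        raise ValueError("no trials")
    fs = trials[0].fs
    L = round_half_up(post_window * fs)
    att, ign = [], []
    for tr in trials:
        if tr.target is None:
            raise ValueError("difference wave needs labeled trials")
        if model is not None:
            sig = tr.X @ model.W[:, :1]
        elif channel is not None:
            sig = tr.X[:, [channel]]
        else:
            sig = tr.X
        per_obj = onsets_to_samples(tr.schedule, tr.fs)
        for e, onsets in enumerate(per_obj):
            bucket = att if e == tr.target else ign
            for t in onsets:
                if t + L <= sig.shape[0]:
                    bucket.append(sig[t : t + L])
    if not att or not ign:
        raise ValueError("no usable events")
    attended = np.mean(att, axis=0)
    ignored = np.mean(ign, axis=0)
    return {
        "times": np.arange(L) / fs,
        "attended": attended,
        "ignored": ignored,
        "difference": attended - ignored,
        "n_attended": len(att),
        "n_ignored": len(ign),
    }
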