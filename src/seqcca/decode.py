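"""Single-trial decoding: rank candidate stimulus sequences against the model.

A trial's channels are projected through the spatial filters to surrogate
channels ``u_k = X w_k``; every object's reference matrix expands the matched
filters to surrogate time courses ``v_{k,e} = Y_e s_k``; the per-object score
is the mean over components of atanh-transformed Pearson correlations, and
the attended object is predicted as the top-ranked score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cca import FilterModel, initial_filter_model
from .preprocess import TrialData
from .reference import ReferenceSet, references_for_trial

__all__ = ["DecodingResult", "project_trial", "score_objects", "predict"]

log = logging.getLogger(__name__)

ATANH_CLAMP = 1.0 - 1e-12


@dataclass
class DecodingResult:
    """Per-object scores and the induced ranking for one trial."""

    scores: np.ndarray  # (m,) mean atanh-correlation per object
    ranking: np.ndarray  # objects sorted by score descending, ties -> lowest index
    predicted: int
    true_target: int | None = None
    per_component_corr: np.ndarray | None = None  # (K, m)

    @property
    def correct(self) -> bool | None:
        if self.true_target is None:
            return None
        return bool(self.predicted == self.true_target)

    @property
    def rank_of_true(self) -> int | None:
        """1-based rank of the labeled target, if any."""
        if self.true_target is None:
            return None
        return int(np.flatnonzero(self.ranking == self.true_target)[0]) + 1


def project_trial(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Surrogate channels ``U = X W``."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"trial has {X.shape[1]} channels but the model expects {W.shape[0]}"
        )
    return X @ W


def _safe_corr(u: np.ndarray, v: np.ndarray) -> float:
    su = u.std()
    sv = v.std()
    if su == 0.0 or sv == 0.0:
        return 0.0
    return float(np.dot(u - u.mean(), v - v.mean()) / (len(u) * su * sv))


def score_objects(
    U: np.ndarray, references: ReferenceSet, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean atanh-correlation score per object.

    Returns ``(scores, per_component_corr)`` where ``per_component_corr`` is
    (K, m).  A zero-variance surrogate time course (possible after heavy
    truncation) contributes a correlation of exactly 0.  Correlations are
    clamped to ``1 - 1e-12`` in magnitude before the atanh transform.
    """
    if S.shape[0] != references.d:
        raise ValueError("matched-filter length inconsistent with the reference set")
    K = S.shape[1]
    m = references.n_objects
    corr = np.zeros((K, m))
    for e in range(m):
        Ye = references[e]
        V = Ye @ S  # (n, K) surrogate time courses for this object
        for k in range(K):
            corr[k, e] = _safe_corr(U[:, k], V[:, k])
    scores = np.arctanh(np.clip(corr, -ATANH_CLAMP, ATANH_CLAMP)).mean(axis=0)
    return scores, corr


def predict(trial: TrialData, model: FilterModel) -> DecodingResult:
    """Decode the attended object of one trial.

    A degenerate model (no retained components) falls back to the untrained
    initial model.  Ties in the score vector break toward the lowest object
    index, deterministically.
    """
    if model.degenerate:
        log.info("degenerate model: falling back to the initial filter model")
        model = initial_filter_model(trial.n_channels, model.d)
    refs = references_for_trial(trial.schedule, trial.fs, trial.n_samples, model.d)
    U = project_trial(trial.X, model.W)
    scores, corr = score_objects(U, refs, model.S)
    ranking = np.argsort(-scores, kind="stable")
    return DecodingResult(
        scores=scores,
        ranking=ranking,
        predicted=int(ranking[0]),
        true_target=trial.target,
        per_component_corr=corr,
    )
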