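"""Joint estimation of spatial filters and matched filters by CCA.

Training trials are concatenated along time into a brain-signal matrix ``X``
(samples x channels) and a reference matrix ``Y`` (samples x d) built from
each trial's *attended* stimulus sequence.  CCA finds channel weightings
``w_k`` (spatial filters) and time-lag weightings ``s_k`` (matched filters)
maximising corr(X w_k, Y s_k); components are retained while their canonical
correlation clears a floor and a sequential chi-square test stays significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .preprocess import TrialData
from .reference import build_reference_set
from .schedule import onsets_to_samples

__all__ = [
    "FilterModel",
    "fit_cca",
    "select_components",
    "train_filter_model",
    "initial_filter_model",
    "channel_subset",
]

log = logging.getLogger(__name__)

DEFAULT_D = 41  # 0.8 s window at 50.863 Hz
DEFAULT_RHO_MIN = 0.1
DEFAULT_ALPHA = 0.05
DEFAULT_RIDGE = 1e-8


@dataclass
class FilterModel:
    """Spatial filters ``W`` (c x K), matched filters ``S`` (d x K), correlations rho."""

    W: np.ndarray
    S: np.ndarray
    rho: np.ndarray
    K: int
    d: int
    channel_labels: list[str] = field(default_factory=list)
    n_train_samples: int = 0
    rho_full: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def degenerate(self) -> bool:
        """True when no component survived selection (decoder falls back)."""
        return self.K == 0


def _inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    vals, vecs = linalg.eigh(C)
    floor = max(vals.max(), 0.0) * 1e-12 + 1e-300
    vals = np.clip(vals, floor, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def fit_cca(
    X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All canonical pairs of (X, Y), correlations descending.

    Columns are centered internally.  Solved by SVD of the whitened
    cross-covariance; each block covariance receives a ridge of
    ``ridge * trace / dim`` so that rank-deficient regimes (many channels,
    few training samples) remain solvable.  Returns ``(W, S, rho)`` with
    ``corr(X @ W[:, k], Y @ S[:, k]) = rho[k]``; the sign of each pair is
    fixed so the extreme value of ``S[:, k]`` is positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    N, c = X.shape
    d = Y.shape[1]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    denom = max(N - 1, 1)
    Cxx = Xc.T @ Xc / denom
    Cyy = Yc.T @ Yc / denom
    Cxy = Xc.T @ Yc / denom
    if ridge:
        Cxx = Cxx + np.eye(c) * ridge * (np.trace(Cxx) / c if np.trace(Cxx) > 0 else 1.0)
        Cyy = Cyy + np.eye(d) * ridge * (np.trace(Cyy) / d if np.trace(Cyy) > 0 else 1.0)
    Wx = _inv_sqrt_psd(Cxx)
    Wy = _inv_sqrt_psd(Cyy)
    U, sv, Vt = linalg.svd(Wx @ Cxy @ Wy, full_matrices=False)
    r = min(c, d)
    W = Wx @ U[:, :r]
    S = Wy @ Vt[:r].T
    rho = np.clip(sv[:r], 0.0, 1.0)
    # sign convention: dominant deflection of the matched filter is positive
    for k in range(r):
        if S[np.argmax(np.abs(S[:, k])), k] < 0:
            S[:, k] *= -1
            W[:, k] *= -1
    return W, S, rho


def select_components(
    rho_full: np.ndarray,
    N: int,
    c: int,
    d: int,
    rho_min: float = DEFAULT_RHO_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> int:
    """Number of leading canonical components to retain.

    Component ``i`` (1-based) is kept while (a) ``rho_i >= rho_min`` and
    (b) Bartlett's sequential chi-square statistic
    ``-(N - 1 - (c + d + 1)/2) * sum_{j>=i} ln(1 - rho_j^2)`` with
    ``(c - i + 1)(d - i + 1)`` degrees of freedom rejects, at level
    ``alpha``, the null that all correlations from ``i`` on are zero.
    Returns the count of the leading run passing both; 0 is valid.
    """
    rho = np.clip(np.asarray(rho_full, dtype=float), 0.0, 1.0 - 1e-12)
    mult = N - 1 - (c + d + 1) / 2.0
    K = 0
    for i in range(len(rho)):
        if rho[i] < rho_min:
            break
        stat = -mult * np.sum(np.log1p(-rho[i:] ** 2))
        df = (c - i) * (d - i)
        if df <= 0 or mult <= 0:
            break
        p = stats.chi2.sf(stat, df)
        if p >= alpha:
            break
        K = i + 1
    return K


def _concat_training(
    trials: list[TrialData], d: int
) -> tuple[np.ndarray, np.ndarray]:
    Xs, Ys = [], []
    for tr in trials:
        if tr.target is None:
            raise ValueError("training trials must carry an attended-object label")
        onsets = onsets_to_samples(tr.schedule, tr.fs)[tr.target]
        refs = build_reference_set([onsets], tr.n_samples, d)
        Xs.append(tr.X)
        Ys.append(refs[0])
    return np.vstack(Xs), np.vstack(Ys)


def train_filter_model(
    trials: list[TrialData],
    d: int = DEFAULT_D,
    rho_min: float = DEFAULT_RHO_MIN,
    alpha: float = DEFAULT_ALPHA,
    ridge: float = DEFAULT_RIDGE,
    standardize: bool = True,
) -> FilterModel:
    """Fit a :class:`FilterModel` from labeled trials.

    Per-trial brain signals and attended-sequence reference matrices are
    concatenated along time; channels are standardized for numerical
    conditioning (the scaling is folded back into ``W`` so the model applies
    to raw trials); CCA is fit and components selected.  A model with
    ``K == 0`` is flagged degenerate and the decoder substitutes the
    untrained initial model.
    """
    if not trials:
        raise ValueError("at least one training trial is required")
    c = trials[0].n_channels
    if any(tr.n_channels != c for tr in trials):
        raise ValueError("trials have inconsistent channel counts")
    X_cat, Y_cat = _concat_training(trials, d)
    scale = np.ones(c)
    if standardize:
        scale = X_cat.std(axis=0)
        scale[scale == 0] = 1.0
    W_full, S_full, rho_full = fit_cca(X_cat / scale, Y_cat, ridge=ridge)
    N = X_cat.shape[0]
    K = select_components(rho_full, N, c, d, rho_min=rho_min, alpha=alpha)
    if K == 0:
        # anticipated under weak/permuted labels; the decoder falls back to
        # the initial model, so this is informational rather than a warning
        log.info("no canonical component survived selection; model is degenerate")
    W = W_full[:, :K] / scale[:, None]
    return FilterModel(
        W=W,
        S=S_full[:, :K],
        rho=rho_full[:K],
        K=K,
        d=d,
        channel_labels=list(trials[0].channel_labels),
        n_train_samples=N,
        rho_full=rho_full,
        provenance={
            "n_trials": len(trials),
            "trial_ids": [(tr.subject_id, tr.run_id) for tr in trials],
            "rho_min": rho_min,
            "alpha": alpha,
            "ridge": ridge,
        },
    )


def initial_filter_model(
    c: int, d: int = DEFAULT_D, channel_labels: list[str] | None = None
) -> FilterModel:
    """Untrained bootstrap model: all-ones spatial filter, triangular template.

    The spatial filter averages across channels and the matched filter is a
    symmetric hat function peaking at the window center — a caricature of an
    evoked deflection that lets the very first trial be decoded before any
    training data exist.
    """
    w = np.ones((c, 1))
    s = np.bartlett(d)[:, None] if d > 1 else np.ones((1, 1))
    return FilterModel(
        W=w,
        S=s,
        rho=np.array([1.0]),
        K=1,
        d=d,
        channel_labels=channel_labels or [f"ch{i}" for i in range(c)],
        provenance={"initial": True},
    )


def channel_subset(
    model: FilterModel,
    trials: list[TrialData],
    n_keep: int,
    **fit_kwargs,
) -> tuple[np.ndarray, FilterModel]:
    """Keep the ``n_keep`` channels with the largest spatial-filter weights, refit.

    Channels are ranked by the maximum over retained components of |w| in
    per-channel standardized units (weight x channel std, so volts-vs-tesla
    scales do not distort the ranking); CCA is then refit on the subset.
    Returns (channel indices kept, refitted model).
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep > model.n_channels:
        raise ValueError("n_keep exceeds the channel count")
    if model.K == 0:
        raise ValueError("cannot rank channels with a degenerate model")
    std = np.vstack([tr.X for tr in trials]).std(axis=0)
    score = np.max(np.abs(model.W * std[:, None]), axis=1)
    keep = np.sort(np.argsort(-score)[:n_keep])
    sub_trials = [
        TrialData(
            X=tr.X[:, keep],
            fs=tr.fs,
            schedule=tr.schedule,
            channel_labels=[tr.channel_labels[i] for i in keep],
            modalities=[tr.modalities[i] for i in keep],
            target=tr.target,
            run_id=tr.run_id,
            subject_id=tr.subject_id,
        )
        for tr in trials
    ]
    refit = train_filter_model(sub_trials, d=model.d, **fit_kwargs)
    return keep, refit
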