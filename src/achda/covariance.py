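"""DA-Ach covariance analyses.

Lag convention: **positive lag means channel A leads channel B** — the
cross-covariance at lag ``l`` pairs ``A(t)`` with ``B(t + l)``.  With DA as
channel A and a delayed negative DA -> Ach interaction, the most negative
covariance therefore appears at a positive lag equal to the interaction
delay (~100 ms).

Two centering modes:

raw
    each channel centred by its session (tensor-wide) mean; covariance then
    reflects the full trial-locked signals.
noise
    each trial centred by its condition's trial-averaged waveform, leaving
    only trial-to-trial fluctuations ("noise correlations").

``cov_matrix`` generalises the lagged covariance to the full two-dimensional
function K(t1, t2) = E_trials[ A(t1) B(t2) ] of centred signals, whose
off-diagonal band at a fixed offset tracks the lagged interaction over the
course of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import TrialTensor


@dataclass
class LagCurve:
    lags_s: np.ndarray  # positive lag: channel A leads channel B
    values: np.ndarray
    mode: str
    n_trials: int
    channels: tuple[str, str] = ("A", "B")
    null_low: np.ndarray | None = None
    null_high: np.ndarray | None = None

    @property
    def argmin_lag_s(self) -> float:
        return float(self.lags_s[int(np.argmin(self.values))])

    @property
    def argmax_lag_s(self) -> float:
        return float(self.lags_s[int(np.argmax(self.values))])


@dataclass
class CovMatrix:
    K: np.ndarray  # t1 (channel A) x t2 (channel B)
    t1: np.ndarray
    t2: np.ndarray
    n_trials: int
    channels: tuple[str, str]
    mode: str


def _check_pair(A: TrialTensor, B: TrialTensor) -> None:
    if A.data.shape != B.data.shape:
        raise ValueError("tensors must share the trial x bin grid")
    if A.bin_width != B.bin_width or A.window != B.window:
        raise ValueError("tensors must share window and bin width")
    if not np.array_equal(A.trial_index, B.trial_index):
        raise ValueError("tensors must cover the same trials")


def condition_mean_residuals(
    tensor: TrialTensor, conditions: np.ndarray | None = None
) -> TrialTensor:
    """Subtract each condition's trial-averaged waveform from its trials."""
    data = tensor.data
    if conditions is None:
        conditions = np.zeros(data.shape[0], dtype=int)
    conditions = np.asarray(conditions)
    out = np.empty_like(data)
    for c in np.unique(conditions):
        sel = conditions == c
        if sel.sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
        out[sel] = data[sel] - data[sel].mean(axis=0, keepdims=True)
    return replace(tensor, data=out)


def _centred(A: TrialTensor, B: TrialTensor, mode: str,
             conditions: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    if mode == "raw":
        return A.data - A.data.mean(), B.data - B.data.mean()
    if mode == "noise":
        return (
            condition_mean_residuals(A, conditions).data,
            condition_mean_residuals(B, conditions).data,
        )
    raise ValueError(f"unknown mode {mode!r}")


def _lag_curve_values(a: np.ndarray, b: np.ndarray, max_bins: int) -> np.ndarray:
    """Covariance at each signed bin lag, averaged over trials and the valid
    (overlapping) bins — no zero padding at the edges."""
    n_bins = a.shape[1]
    vals = np.empty(2 * max_bins + 1)
    for i, l in enumerate(range(-max_bins, max_bins + 1)):
        if l >= 0:
            prod = a[:, : n_bins - l] * b[:, l:]
        else:
            prod = a[:, -l:] * b[:, : n_bins + l]
        vals[i] = prod.mean()
    return vals


def crosscov_lagged(
    A: TrialTensor,
    B: TrialTensor,
    max_lag: float,
    mode: str = "noise",
    conditions: np.ndarray | None = None,
) -> LagCurve:
    """Trial-averaged lagged cross-covariance between two aligned channels."""
    _check_pair(A, B)
    max_bins = int(round(max_lag / A.bin_width))
    if max_bins >= A.n_bins:
        raise ValueError("max_lag exceeds the tensor window")
    a, b = _centred(A, B, mode, conditions)
    lags = np.arange(-max_bins, max_bins + 1) * A.bin_width
    return LagCurve(
        lags_s=lags,
        values=_lag_curve_values(a, b, max_bins),
        mode=mode,
        n_trials=A.n_trials,
        channels=(A.channel, B.channel),
    )


def cov_matrix(
    A: TrialTensor,
    B: TrialTensor,
    mode: str = "noise",
    conditions: np.ndarray | None = None,
) -> CovMatrix:
    """Two-dimensional covariance K(t1, t2) across aligned trials."""
    _check_pair(A, B)
    if A.n_trials < 3:
        raise ValueError("cov_matrix needs at least 3 trials")
    if A.n_trials < 10:
        import warnings

        warnings.warn("fewer than 10 trials; K(t1, t2) will be very noisy")
    a, b = _centred(A, B, mode, conditions)
    K = a.T @ b / A.n_trials
    return CovMatrix(
        K=K,
        t1=A.bin_centers,
        t2=B.bin_centers,
        n_trials=A.n_trials,
        channels=(A.channel, B.channel),
        mode=mode,
    )


def off_diagonal(
    K: CovMatrix, offset: float, band_halfwidth: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of K(t1, t2) over the band t2 in [t1+offset-w, t1+offset+w].

    Returns ``(t1, values)``; t1 bins whose band falls entirely outside the
    matrix yield NaN (edge truncation).
    """
    bw = float(K.t1[1] - K.t1[0])
    span = K.t2[-1] - K.t2[0]
    if abs(offset) > span:
        raise ValueError("offset lies outside the matrix span")
    off_bins = int(round(offset / bw))
    w_bins = int(round(band_halfwidth / bw))
    n1, n2 = K.K.shape
    vals = np.full(n1, np.nan)
    for i in range(n1):
        j0 = i + off_bins - w_bins
        j1 = i + off_bins + w_bins + 1
        j0c, j1c = max(j0, 0), min(j1, n2)
        if j1c > j0c:
            vals[i] = K.K[i, j0c:j1c].mean()
    return K.t1, vals


def null_controls(
    A: TrialTensor,
    B: TrialTensor,
    max_lag: float,
    mode: str = "circular_shift",
    centering: str = "noise",
    conditions: np.ndarray | None = None,
    sessions: np.ndarray | None = None,
    n_perm: int = 500,
    seed: int = 0,
    band: str = "pointwise",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation null band for the lagged cross-covariance.

    ``circular_shift``: every trial of channel B is circularly shifted in
    time by an independent random number of bins per permutation.
    ``session_swap``: channel B trials are re-paired with trials drawn from a
    *different* session (requires ``sessions`` labels covering >= 2 sessions).

    Returns ``(lags_s, low, high)``.  ``band="pointwise"`` gives per-lag
    2.5/97.5 percentiles; ``band="simultaneous"`` gives a max-statistic band
    (percentiles of the per-permutation extremes across lags), which controls
    the family-wise rate for "any lag outside" statements.
    """
    _check_pair(A, B)
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives unstable 95% bands")
    rng = np.random.default_rng(seed)
    max_bins = int(round(max_lag / A.bin_width))
    a, b = _centred(A, B, centering, conditions)
    n_t, n_b = a.shape

    if mode == "session_swap":
        if sessions is None or len(np.unique(sessions)) < 2:
            raise ValueError("session_swap requires >= 2 sessions")
        sessions = np.asarray(sessions)

    curves = np.empty((n_perm, 2 * max_bins + 1))
    for p in range(n_perm):
        if mode == "circular_shift":
            shifts = rng.integers(1, n_b, size=n_t)
            bp = np.empty_like(b)
            for i, s in enumerate(shifts):
                bp[i] = np.roll(b[i], s)
        elif mode == "session_swap":
            pairing = np.empty(n_t, dtype=int)
            for i in range(n_t):
                pool = np.flatnonzero(sessions != sessions[i])
                pairing[i] = pool[rng.integers(len(pool))]
            bp = b[pairing]
        else:
            raise ValueError(f"unknown null mode {mode!r}")
        curves[p] = _lag_curve_values(a, bp, max_bins)
    lags = np.arange(-max_bins, max_bins + 1) * A.bin_width
    if band == "simultaneous":
        lo = float(np.percentile(curves.min(axis=1), 2.5))
        hi = float(np.percentile(curves.max(axis=1), 97.5))
        return lags, np.full_like(lags, lo), np.full_like(lags, hi)
    if band != "pointwise":
        raise ValueError(f"unknown band {band!r}")
    low, high = np.percentile(curves, [2.5, 97.5], axis=0)
    return lags, low, high
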