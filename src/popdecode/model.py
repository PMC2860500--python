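"""Minimal single-unit encoding model: predicted transition correlations and
reverse-correlation estimation of the temporal response function.

The model asks what image is linearly available in the firing of an
average unit after a pattern transition A -> B.  Because each pixel's
drive is the luminance-contrast time course convolved with the shared
temporal kernel, the population-encoded image at time ``t`` after the
transition is a weighted sum of the two patterns,

    encoded(t) = (I - K(t)) * A + K(t) * B,

where ``K(t)`` is the kernel's running integral and ``I`` its total
integral.  With a biphasic kernel, ``I - K(t)`` swings negative during
the transient, so the encoded image transiently resembles the difference
pattern B - A before settling on the (weakly sustained) current pattern.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .kernels import TemporalResponseFunction
from .stimuli import PatternMatrix, normalize_columns, pattern_matrix
from .traces import CorrelationTrace

__all__ = [
    "model_correlation_timecourse",
    "reverse_correlate",
    "ReverseCorrelationEstimator",
]


def model_correlation_timecourse(
    trp: TemporalResponseFunction,
    patterns: PatternMatrix | None = None,
    step_ms: float | None = None,
) -> CorrelationTrace:
    """Average correlation time course over all 81 x 81 pattern transitions.

    For every ordered pair (A, B) the encoded 2x2 image after the
    transition is correlated, per time sample, with the normalized
    previous pattern A, current pattern B, and difference pattern B - A,
    then averaged over all pairs.  Identity transitions have a zero
    difference vector and contribute correlation 0 to the difference
    average by the normalization convention.
    """
    if patterns is None:
        patterns = pattern_matrix()
    raw = patterns.raw                     # (P, 4)
    P = raw.shape[0]

    cum = trp.cumulative
    total = cum[-1]
    times = trp.lags_ms
    if step_ms is not None:
        stride = max(1, int(round(step_ms / trp.frame_ms)))
        idx = np.arange(0, cum.size, stride)
        cum, times = cum[idx], times[idx]

    a_hat = normalize_columns(raw.T).T                       # (P, 4)
    diff = raw[None, :, :] - raw[:, None, :]                 # (P, P, 4), B - A
    d_flat = diff.reshape(-1, 4)
    diff_hat = normalize_columns(d_flat.T).T.reshape(P, P, 4)

    n_pairs = P * P
    mean_prev = np.empty(cum.size)
    mean_cur = np.empty(cum.size)
    mean_diff = np.empty(cum.size)
    sem_prev = np.empty(cum.size)
    sem_cur = np.empty(cum.size)
    sem_diff = np.empty(cum.size)
    for i, beta in enumerate(cum):
        alpha = total - beta
        enc = alpha * raw[:, None, :] + beta * raw[None, :, :]   # (P, P, 4)
        enc_hat = normalize_columns(enc.reshape(-1, 4).T).T.reshape(P, P, 4)
        c_prev = np.einsum("abl,al->ab", enc_hat, a_hat)
        c_cur = np.einsum("abl,bl->ab", enc_hat, a_hat)
        c_diff = np.einsum("abl,abl->ab", enc_hat, diff_hat)
        for arr, mean, sem in (
            (c_prev, mean_prev, sem_prev),
            (c_cur, mean_cur, sem_cur),
            (c_diff, mean_diff, sem_diff),
        ):
            mean[i] = arr.mean()
            sem[i] = arr.std(ddof=1) / np.sqrt(n_pairs)
    return CorrelationTrace(
        time_ms=times,
        mean_previous=mean_prev,
        mean_current=mean_cur,
        mean_difference=mean_diff,
        sem_previous=sem_prev,
        sem_current=sem_cur,
        sem_difference=sem_diff,
        n=n_pairs,
    )


def reverse_correlate(
    stimulus: np.ndarray,
    counts: np.ndarray,
    frame_ms: float = 8.3,
    max_lag_ms: float = 200.0,
    on_pixels: np.ndarray | None = None,
    off_pixels: np.ndarray | None = None,
) -> TemporalResponseFunction:
    """Spike-triggered-average estimate of the temporal response function.

    ``stimulus`` is (n_frames, n_pixels) zero-mean white noise at
    ``frame_ms`` resolution, ``counts`` the unit's spike counts per frame.
    The per-pixel STA over lags 0..``max_lag_ms`` is averaged across the
    unit's driving pixels (OFF pixels sign-flipped) and normalized to unit
    peak.  Defaults mirror an 8.3 ms frame white-noise mapping stimulus.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if stimulus.ndim != 2 or counts.shape != (stimulus.shape[0],):
        raise ValueError("stimulus must be (n_frames, n_pixels) with one count per frame")
    total = counts.sum()
    if total <= 0:
        raise ValueError("kernel is unestimable: no spikes in the response")
    n_frames, n_pixels = stimulus.shape
    n_lags = int(round(max_lag_ms / frame_ms)) + 1
    sta = np.zeros((n_lags, n_pixels))
    for lag in range(n_lags):
        if lag >= n_frames:
            break
        sta[lag] = counts[lag:] @ stimulus[: n_frames - lag] / total
    if on_pixels is None and off_pixels is None:
        on_pixels = np.arange(n_pixels)
    parts = []
    if on_pixels is not None and len(on_pixels) > 0:
        parts.append(sta[:, np.asarray(on_pixels, dtype=int)])
    if off_pixels is not None and len(off_pixels) > 0:
        parts.append(-sta[:, np.asarray(off_pixels, dtype=int)])
    kernel = np.concatenate(parts, axis=1).mean(axis=1)
    peak = np.abs(kernel).max()
    if peak > 0:
        kernel = kernel / peak
    return TemporalResponseFunction(kernel=kernel, frame_ms=frame_ms)


class ReverseCorrelationEstimator(BaseEstimator):
    """sklearn-style wrapper around :func:`reverse_correlate`.

    Parameters
    ----------
    frame_ms : float
        Duration of one white-noise frame.
    max_lag_ms : float
        Last lag of the estimated kernel.
    on_pixels, off_pixels : array-like of int or None
        Indices of the unit's driving pixels.  OFF pixels enter the
        average sign-flipped.  With both None, all pixels are treated
        as ON.

    Attributes
    ----------
    kernel_ : TemporalResponseFunction
        Peak-normalized kernel estimate.
    sta_ : ndarray of shape (n_lags, n_pixels)
        Raw per-pixel spike-triggered average.
    """

    def __init__(self, frame_ms=8.3, max_lag_ms=200.0, on_pixels=None, off_pixels=None):
        self.frame_ms = frame_ms
        self.max_lag_ms = max_lag_ms
        self.on_pixels = on_pixels
        self.off_pixels = off_pixels

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.kernel_ = reverse_correlate(
            X, y,
            frame_ms=self.frame_ms,
            max_lag_ms=self.max_lag_ms,
            on_pixels=self.on_pixels,
            off_pixels=self.off_pixels,
        )
        total = y.sum()
        n_lags = int(round(self.max_lag_ms / self.frame_ms)) + 1
        sta = np.zeros((n_lags, X.shape[1]))
        for lag in range(n_lags):
            if lag >= X.shape[0]:
                break
            sta[lag] = y[lag:] @ X[: X.shape[0] - lag] / total
        self.sta_ = sta
        return self
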