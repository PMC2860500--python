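"""Correlation-weighted dictionary decoding of population rate vectors.

The population code is a dictionary matrix ``RR`` (patterns x recording
sites) of mean firing rates measured in the blank-separated dictionary
paradigm.  Row-normalizing ``RR`` (subtract the row mean, divide by the
centered Euclidean norm) gives ``R``, in which the matrix product with a
normalized instantaneous population vector ``r`` yields the Pearson
correlation of ``r`` with every pattern's template.  The decoded image is
the correlation-weighted average of the (normalized) stimulus patterns,

    d_l = sum_p c_p * S_pl,    c = R r,

normalized again so that correlating ``d`` with the previous pattern A,
the current pattern B, or the difference pattern B - A is a plain dot
product.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .population import SpikeCountTensor
from .stimuli import (
    BLANK,
    PatternMatrix,
    TrialSchedule,
    contrast_of,
    normalize_columns,
    normalize_vector,
    pattern_matrix,
    transitions,
)
from .traces import CorrelationTrace

__all__ = [
    "DictionaryMatrix",
    "build_dictionary",
    "significance_mask",
    "decode_instant",
    "correlation_timecourse",
    "crossover_time",
    "window_split_consistency",
    "DictionaryDecoder",
]

#: Dictionary averaging windows used throughout (ms after pattern onset).
WINDOWS = ((0.0, 90.0), (90.0, 250.0), (0.0, 250.0))


@dataclass
class DictionaryMatrix:
    """P x N population code: mean rates ``RR`` and row-normalized ``R``."""

    RR: np.ndarray
    R: np.ndarray
    window: tuple[float, float]
    pattern_ids: np.ndarray
    n_repeats: int

    def to_csv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.RR, columns=[f"site_{n}" for n in range(self.RR.shape[1])])
        frame.insert(0, "pattern_id", self.pattern_ids)
        with open(path, "w") as fh:
            fh.write(f"# window_ms={self.window[0]}-{self.window[1]} n_repeats={self.n_repeats}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "DictionaryMatrix":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            frame = pd.read_csv(StringIO(fh.read()))
        meta = dict(kv.split("=") for kv in header.split())
        lo, hi = meta["window_ms"].split("-")
        RR = frame.drop(columns="pattern_id").to_numpy(float)
        return cls(
            RR=RR,
            R=normalize_columns(RR.T).T,
            window=(float(lo), float(hi)),
            pattern_ids=frame["pattern_id"].to_numpy(int),
            n_repeats=int(meta["n_repeats"]),
        )


def _window_bins(window, bin_ms, n_bins):
    lo, hi = window
    b0, b1 = lo / bin_ms, hi / bin_ms
    if not (float(b0).is_integer() and float(b1).is_integer()):
        raise ValueError(f"window {window} is not aligned to {bin_ms} ms bins")
    b0, b1 = int(b0), int(b1)
    if not 0 <= b0 < b1 <= n_bins:
        raise ValueError(f"window {window} outside the 0-{n_bins * bin_ms} ms period")
    return b0, b1


def build_dictionary(
    tensor: SpikeCountTensor,
    schedule: TrialSchedule,
    window: tuple[float, float] = (0.0, 250.0),
) -> DictionaryMatrix:
    """Average dictionary-paradigm rates into the P x N matrix ``RR``.

    ``RR[p, n]`` is site ``n``'s mean firing rate (spikes/s) over the
    window after onset of pattern ``p``, averaged across all repetitions.
    Rates rather than raw counts keep different windows comparable; the
    row normalization makes the overall scale irrelevant.
    """
    b0, b1 = _window_bins(window, tensor.bin_ms, tensor.n_bins)
    rates = tensor.rates()
    pattern_ids = sorted({p.pattern_id for p in schedule.pattern_periods()})
    RR = np.empty((len(pattern_ids), tensor.n_sites))
    for row, pid in enumerate(pattern_ids):
        idx = [p.index for p in schedule.pattern_periods() if p.pattern_id == pid]
        if not idx:
            raise ValueError(f"pattern {pid} missing from schedule")
        RR[row] = rates[:, b0:b1, idx].mean(axis=(1, 2))
    n_repeats = len(schedule.pattern_periods()) // len(pattern_ids)
    return DictionaryMatrix(
        RR=RR,
        R=normalize_columns(RR.T).T,
        window=window,
        pattern_ids=np.asarray(pattern_ids),
        n_repeats=n_repeats,
    )


def significance_mask(
    tensor: SpikeCountTensor,
    schedule: TrialSchedule,
    baseline_ms: float = 100.0,
) -> np.ndarray:
    """Responsiveness criterion per site, from the dictionary paradigm.

    A site is significant iff its mean evoked rate (across patterns and
    time) strictly exceeds the baseline mean plus two baseline standard
    deviations.  The baseline is the trial-averaged PSTH rate in the last
    ``baseline_ms`` of the blank periods (the pre-onset window); its mean
    and standard deviation are taken across those baseline time bins.
    """
    rates = tensor.rates()
    blank_idx = [p.index for p in schedule.periods if p.pattern_id == BLANK]
    if not blank_idx:
        raise ValueError("schedule has no blank periods to provide a baseline")
    nb = int(round(baseline_ms / tensor.bin_ms))
    if nb < 1:
        raise ValueError("baseline window shorter than one bin")
    psth = rates[:, tensor.n_bins - nb :, blank_idx].mean(axis=2)   # (N, nb)
    pattern_idx = [p.index for p in schedule.pattern_periods()]
    evoked = rates[:, :, pattern_idx].mean(axis=(1, 2))
    return evoked > psth.mean(axis=1) + 2.0 * psth.std(axis=1, ddof=0)


def decode_instant(
    rr: np.ndarray,
    dictionary: DictionaryMatrix,
    patterns: PatternMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Decode one instantaneous population vector.

    Returns ``(c, d, best_id)``: the correlation of the normalized vector
    with every dictionary row, the normalized correlation-weighted decoded
    pattern, and the max-correlation pattern id (the simple decoding
    variant).
    """
    if patterns is None:
        patterns = pattern_matrix()
    rr = np.asarray(rr, dtype=float)
    if rr.shape != (dictionary.R.shape[1],):
        raise ValueError(
            f"population vector has {rr.shape[0] if rr.ndim else 0} sites, "
            f"dictionary expects {dictionary.R.shape[1]}"
        )
    r = normalize_vector(rr)
    c = dictionary.R @ r
    d = normalize_vector(patterns.S.T @ c)
    best = int(dictionary.pattern_ids[int(np.argmax(c))])
    return c, d, best


def _decode_bins(counts_bin, dictionary, patterns):
    """Vectorized decoding of many population vectors (columns)."""
    r = normalize_columns(counts_bin)          # (N, M)
    c = dictionary.R @ r                       # (P, M)
    d = normalize_columns(patterns.S.T @ c)    # (4, M)
    return c, d


def correlation_timecourse(
    tensor: SpikeCountTensor,
    schedule: TrialSchedule,
    dictionary: DictionaryMatrix,
    patterns: PatternMatrix | None = None,
) -> CorrelationTrace:
    """Correlation of the decoded pattern with previous/current/difference
    patterns, per time bin, averaged over all transitions of the schedule.

    Identity transitions (zero difference vector) contribute correlation 0
    to the difference average, consistent with the normalization
    convention for contrast-free patterns.
    """
    if patterns is None:
        patterns = pattern_matrix()
    trans = transitions(schedule)
    idx = np.array([t.period_index for t in trans])
    prev = normalize_columns(np.stack([contrast_of(t.previous_id) for t in trans], axis=1))
    cur = normalize_columns(np.stack([contrast_of(t.current_id) for t in trans], axis=1))
    diff = normalize_columns(
        np.stack(
            [contrast_of(t.current_id) - contrast_of(t.previous_id) for t in trans], axis=1
        )
    )
    n = len(trans)
    nb = tensor.n_bins
    means = np.empty((3, nb))
    sems = np.empty((3, nb))
    for b in range(nb):
        _, d = _decode_bins(tensor.counts[:, b, idx].astype(float), dictionary, patterns)
        for row, target in enumerate((prev, cur, diff)):
            corr = np.sum(d * target, axis=0)
            means[row, b] = corr.mean()
            sems[row, b] = corr.std(ddof=1) / np.sqrt(n)
    return CorrelationTrace(
        time_ms=tensor.bin_centers_ms,
        mean_previous=means[0],
        mean_current=means[1],
        mean_difference=means[2],
        sem_previous=sems[0],
        sem_current=sems[1],
        sem_difference=sems[2],
        n=n,
    )


def crossover_time(trace: CorrelationTrace, k: int = 3) -> float | None:
    """Time at which the current-pattern correlation overtakes the
    difference-pattern correlation after the transient.

    Returns the first bin, *after difference dominance has been
    established*, at which the current-pattern mean correlation exceeds
    the difference-pattern mean correlation and stays larger for ``k``
    consecutive bins; ``None`` if the difference correlation never
    dominates or never hands over.  (Before the response to the new
    stimulus begins, the current correlation trivially sits at ~0 above a
    negative difference correlation; that pre-response region is not a
    crossover.)
    """
    dominated = trace.mean_difference > trace.mean_current
    if not dominated.any():
        return None
    start = int(np.argmax(dominated))
    above = trace.mean_current > trace.mean_difference
    run = 0
    for i in range(start, above.size):
        run = run + 1 if above[i] else 0
        if run == k:
            return float(trace.time_ms[i - k + 1])
    return None


def window_split_consistency(
    relay_tensor: SpikeCountTensor,
    relay_schedule: TrialSchedule,
    dict_tensor: SpikeCountTensor,
    dict_schedule: TrialSchedule,
    patterns: PatternMatrix | None = None,
    windows: tuple = ((0.0, 90.0), (90.0, 250.0)),
) -> tuple[CorrelationTrace, CorrelationTrace, float]:
    """Decode the relay data with dictionaries from two averaging windows.

    Returns the two correlation traces plus the Pearson correlation
    between their difference-minus-current time courses; a common
    population code across the two windows yields strongly positively
    correlated traces.
    """
    traces = []
    for window in windows:
        dictionary = build_dictionary(dict_tensor, dict_schedule, window=window)
        traces.append(correlation_timecourse(relay_tensor, relay_schedule, dictionary, patterns))
    a = traces[0].mean_difference - traces[0].mean_current
    b = traces[1].mean_difference - traces[1].mean_current
    r = float(stats.pearsonr(a, b).statistic)
    return traces[0], traces[1], r


class DictionaryDecoder(BaseEstimator):
    """Template-matching population decoder (sklearn-style estimator).

    Parameters
    ----------
    window : tuple of float
        Dictionary averaging window in ms after pattern onset; the study
        windows are (0, 90), (90, 250) and (0, 250).
    crossover_k : int
        Persistence (consecutive bins) required by :meth:`crossover`.

    Attributes
    ----------
    dictionary_ : DictionaryMatrix
        The fitted population code (``RR`` and its normalized form).
    pattern_matrix_ : PatternMatrix
        Normalized contrast codes of the stimulus set.
    significance_mask_ : ndarray of bool
        Per-site responsiveness flags from the fitting data.
    """

    def __init__(self, window=(0.0, 250.0), crossover_k=3):
        self.window = window
        self.crossover_k = crossover_k

    def fit(self, X: SpikeCountTensor, y: TrialSchedule):
        """Build the dictionary from a dictionary-paradigm tensor ``X`` and
        its schedule ``y``."""
        self.pattern_matrix_ = pattern_matrix()
        self.dictionary_ = build_dictionary(X, y, window=tuple(self.window))
        self.significance_mask_ = significance_mask(X, y)
        return self

    def decode(self, rr: np.ndarray):
        return decode_instant(rr, self.dictionary_, self.pattern_matrix_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Max-correlation pattern ids for population vectors in the rows
        of ``X`` (n_samples, n_sites)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        c = self.dictionary_.R @ normalize_columns(X.T)
        return self.dictionary_.pattern_ids[np.argmax(c, axis=0)]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Normalized decoded patterns (n_samples, 4) for population
        vectors in the rows of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, d = _decode_bins(X.T, self.dictionary_, self.pattern_matrix_)
        return d.T

    def trace(self, X: SpikeCountTensor, y: TrialSchedule) -> CorrelationTrace:
        return correlation_timecourse(X, y, self.dictionary_, self.pattern_matrix_)

    def crossover(self, X: SpikeCountTensor, y: TrialSchedule) -> float | None:
        return crossover_time(self.trace(X, y), k=self.crossover_k)
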