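"""Mutual information between spike counts and stimulus identity.

Per recording site and time bin, single-trial spike counts are
discretized into four equal-width intervals spanning the observed count
range (e.g. a 0-7 range gives intervals 0-1, 2-3, 4-5, 6-7), a joint
distribution P(r, s) over count interval r and stimulus s is tallied, and
the mutual information

    I = sum_{r,s} P(r,s) * log2( P(r,s) / (P(r) P(s)) )

is computed.  The small-sample (firing-rate) bias is corrected by
subtracting the mean information obtained after randomly permuting the
stimulus labels; the corrected value can be slightly negative by
construction.  Information about the *previous* stimulus pairs each
stimulus label with the counts observed one full 250 ms period later.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .decoder import significance_mask
from .population import SpikeCountTensor
from .stimuli import BLANK, TrialSchedule
from .traces import InfoTrace

__all__ = [
    "bin_counts",
    "mutual_information",
    "information",
    "corrected_information",
    "previous_stimulus_information",
    "information_trace",
    "TransitionInformation",
]

N_INTERVALS = 4


def bin_counts(counts: np.ndarray, n_intervals: int = N_INTERVALS) -> np.ndarray:
    """Assign spike counts to equal-width intervals over [min, max + 1).

    The interval width is (max - min + 1) / n_intervals on a continuous
    axis, with floor assignment; for the 0-7 range this reproduces the
    intervals 0-1, 2-3, 4-5, 6-7.  A degenerate range (all counts equal)
    puts everything in interval 0.
    """
    counts = np.asarray(counts)
    if counts.size < 1:
        raise ValueError("need at least one trial")
    lo = counts.min()
    hi = counts.max()
    if hi == lo:
        return np.zeros(counts.shape, dtype=int)
    width = (hi - lo + 1) / n_intervals
    labels = np.floor((counts - lo) / width).astype(int)
    return np.clip(labels, 0, n_intervals - 1)


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information (bits) of a joint distribution P(r, s).

    Zero-probability cells contribute 0 (the 0 * log 0 convention).
    """
    joint = np.asarray(joint, dtype=float)
    if np.any(joint < 0) or not np.isclose(joint.sum(), 1.0, atol=1e-8):
        raise ValueError("joint must be a probability distribution summing to 1")
    pr = joint.sum(axis=1, keepdims=True)
    ps = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / (pr * ps), 1.0)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(terms.sum())


def _joint_from_samples(labels: np.ndarray, stimuli: np.ndarray) -> np.ndarray:
    n_r = int(labels.max()) + 1 if labels.size else 1
    cats, s_idx = np.unique(stimuli, return_inverse=True)
    joint = np.zeros((max(n_r, N_INTERVALS), cats.size))
    np.add.at(joint, (labels, s_idx), 1.0)
    return joint / joint.sum()


def information(counts: np.ndarray, stimuli: np.ndarray) -> float:
    """Raw (uncorrected) information from single-trial counts and labels."""
    labels = bin_counts(counts)
    return mutual_information(_joint_from_samples(labels, np.asarray(stimuli)))


def corrected_information(
    counts: np.ndarray,
    stimuli: np.ndarray,
    n_shuffles: int = 20,
    rng: np.random.Generator | None = None,
) -> float:
    """Shuffle-bias-corrected information.

    The information recomputed after randomly permuting the stimulus
    labels measures the positive bias of the plug-in estimator at this
    sample size; its mean over ``n_shuffles`` permutations is subtracted
    from the raw value.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    stimuli = np.asarray(stimuli)
    labels = bin_counts(counts)
    raw = mutual_information(_joint_from_samples(labels, stimuli))
    bias = np.mean(
        [
            mutual_information(_joint_from_samples(labels, rng.permutation(stimuli)))
            for _ in range(n_shuffles)
        ]
    )
    return raw - float(bias)


def _relay_samples(tensor, schedule, site, time_bin, shift=0):
    """Single-trial counts and stimulus labels for one site and time bin.

    ``shift`` = 0 pairs each pattern's label with its own counts; ``shift``
    = m pairs the label with the counts observed m periods (m x 250 ms)
    later, dropping transitions whose shifted period does not exist or is
    a blank.
    """
    periods = schedule.periods
    counts, labels = [], []
    for i, p in enumerate(periods):
        if p.pattern_id == BLANK:
            continue
        j = i + shift
        if j >= len(periods) or periods[j].pattern_id == BLANK:
            continue
        counts.append(tensor.counts[site, time_bin, periods[j].index])
        labels.append(p.pattern_id)
    return np.asarray(counts), np.asarray(labels)


def previous_stimulus_information(
    tensor: SpikeCountTensor,
    schedule: TrialSchedule,
    site: int,
    time_bin: int,
    n_shuffles: int = 20,
    shift: int = 1,
    rng: np.random.Generator | None = None,
) -> float:
    """Corrected information about the stimulus shown ``shift`` periods
    earlier, i.e. counting spikes at time t + shift * 250 ms."""
    counts, labels = _relay_samples(tensor, schedule, site, time_bin, shift=shift)
    return corrected_information(counts, labels, n_shuffles=n_shuffles, rng=rng)


def information_trace(
    tensor: SpikeCountTensor,
    schedule: TrialSchedule,
    sites: np.ndarray | None = None,
    n_shuffles: int = 20,
    rng: np.random.Generator | None = None,
) -> InfoTrace:
    """Mean corrected information per time bin across the included sites,
    about both the current and the previous stimulus."""
    if rng is None:
        rng = np.random.default_rng()
    if sites is None:
        sites = np.arange(tensor.n_sites)
    sites = np.asarray(sites)
    if sites.dtype == bool:
        sites = np.flatnonzero(sites)
    cur = np.zeros((sites.size, tensor.n_bins))
    prev = np.zeros((sites.size, tensor.n_bins))
    for si, site in enumerate(sites):
        for b in range(tensor.n_bins):
            counts, labels = _relay_samples(tensor, schedule, site, b, shift=0)
            cur[si, b] = corrected_information(counts, labels, n_shuffles, rng)
            counts, labels = _relay_samples(tensor, schedule, site, b, shift=1)
            prev[si, b] = corrected_information(counts, labels, n_shuffles, rng)
    return InfoTrace(
        time_ms=tensor.bin_centers_ms,
        info_current_bits=cur.mean(axis=0),
        info_previous_bits=prev.mean(axis=0),
        n_sites=int(sites.size),
    )


class TransitionInformation(BaseEstimator):
    """Per-site, per-bin information about current and previous stimuli.

    Parameters
    ----------
    n_shuffles : int
        Number of stimulus-label permutations for the bias correction.
    significant_only : bool
        Restrict the trace average to sites passing the responsiveness
        criterion measured on the dictionary-paradigm data passed to
        :meth:`fit`.
    random_state : int or None
        Seed for the permutation generator.

    Attributes
    ----------
    trace_ : InfoTrace
        Mean corrected information per bin across included sites.
    sites_ : ndarray
        Indices of the sites entering the average.
    """

    def __init__(self, n_shuffles=20, significant_only=True, random_state=None):
        self.n_shuffles = n_shuffles
        self.significant_only = significant_only
        self.random_state = random_state

    def fit(
        self,
        X: SpikeCountTensor,
        y: TrialSchedule,
        dictionary_data: tuple[SpikeCountTensor, TrialSchedule] | None = None,
    ):
        """Estimate information traces from a relay tensor ``X`` and its
        schedule ``y``; ``dictionary_data`` supplies the responsiveness
        screen when ``significant_only`` is set."""
        rng = np.random.default_rng(self.random_state)
        if self.significant_only and dictionary_data is not None:
            mask = significance_mask(*dictionary_data)
            self.sites_ = np.flatnonzero(mask)
        else:
            self.sites_ = np.arange(X.n_sites)
        self.trace_ = information_trace(
            X, y, sites=self.sites_, n_shuffles=self.n_shuffles, rng=rng
        )
        return self
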