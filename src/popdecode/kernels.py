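"""Temporal response kernels and the linear encoding stage.

The minimal encoding model treats each pixel (or tile) independently: the
luminance-contrast time course of a pixel is convolved with one temporal
response function shared by the population.  ON subregions add the
convolved signal, OFF subregions subtract it, and the resulting scalar
drive stands in for the membrane potential of a simple-cell-like unit.

The default kernel is biphasic -- a fast positive lobe followed by a
slower, weaker negative lobe -- the shape reverse correlation recovers
from adapted early visual neurons.  Because the negative lobe does not
fully cancel the positive one (net integral slightly positive), a
sustained stimulus keeps a small standing representation while the
transient after a change transiently encodes the stimulus *difference*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TemporalResponseFunction",
    "biphasic_kernel",
    "encode_pixel",
    "unit_drive",
]


@dataclass(frozen=True)
class TemporalResponseFunction:
    """A sampled temporal kernel.

    Sign convention: a positive kernel value means a luminance-contrast
    increment depolarizes an ON subregion at that lag.
    """

    kernel: np.ndarray
    frame_ms: float

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size == 0:
            raise ValueError("kernel must be a non-empty 1-D array")
        if not np.all(np.isfinite(k)):
            raise ValueError("kernel must be finite")
        object.__setattr__(self, "kernel", k)

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(self.kernel.size) * self.frame_ms

    @property
    def cumulative(self) -> np.ndarray:
        """Running integral (step response) in kernel-sample units."""
        return np.cumsum(self.kernel)

    @property
    def integral(self) -> float:
        return float(self.kernel.sum())

    def resampled(self, frame_ms: float) -> "TemporalResponseFunction":
        """Linear-interpolation resampling, rescaled so the integral
        (in ms units) is preserved."""
        if frame_ms == self.frame_ms:
            return self
        t_new = np.arange(0.0, self.lags_ms[-1] + 0.5 * frame_ms, frame_ms)
        k_new = np.interp(t_new, self.lags_ms, self.kernel)
        k_new *= frame_ms / self.frame_ms
        return TemporalResponseFunction(kernel=k_new, frame_ms=frame_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ms": self.lags_ms, "value": self.kernel})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemporalResponseFunction":
        frame = pd.read_csv(path)
        lags = frame["lag_ms"].to_numpy(dtype=float)
        frame_ms = float(lags[1] - lags[0]) if lags.size > 1 else 1.0
        return cls(kernel=frame["value"].to_numpy(dtype=float), frame_ms=frame_ms)


def _gamma_lobe(t: np.ndarray, peak_ms: float, shape: int) -> np.ndarray:
    """Gamma-shaped lobe with unit peak at ``peak_ms``."""
    x = np.clip(t / peak_ms, 0.0, None)
    return x**shape * np.exp(shape * (1.0 - x))


def biphasic_kernel(
    frame_ms: float = 1.0,
    duration_ms: float = 250.0,
    peak_pos_ms: float = 50.0,
    peak_neg_ms: float = 85.0,
    shape_pos: int = 3,
    shape_neg: int = 8,
    neg_fraction: float = 0.95,
) -> TemporalResponseFunction:
    """Default biphasic temporal response function.

    ``neg_fraction`` is the ratio of the negative lobe's integral to the
    positive lobe's; values < 1 leave the net integral slightly positive,
    so a constant stimulus retains a small sustained representation while
    the early transient encodes the stimulus change.  The kernel is
    normalized to unit peak.
    """
    if not 0.0 <= neg_fraction:
        raise ValueError("neg_fraction must be non-negative")
    t = np.arange(0.0, duration_ms, frame_ms)
    pos = _gamma_lobe(t, peak_pos_ms, shape_pos)
    neg = _gamma_lobe(t, peak_neg_ms, shape_neg)
    amp_neg = neg_fraction * pos.sum() / neg.sum()
    k = pos - amp_neg * neg
    k /= np.abs(k).max()
    return TemporalResponseFunction(kernel=k, frame_ms=frame_ms)


def encode_pixel(sis: np.ndarray, trp: TemporalResponseFunction) -> np.ndarray:
    """Causal convolution of per-pixel contrast time courses with the kernel.

    ``sis`` has time on the last axis (any leading pixel axes); history
    before the first sample is zero-padded (gray screen before the
    session).  The output has the same shape; sample ``t`` depends only on
    inputs at times <= ``t``.
    """
    sis = np.asarray(sis, dtype=float)
    n = sis.shape[-1]
    k = trp.kernel
    shape = (1,) * (sis.ndim - 1) + (k.size,)
    out = signal.fftconvolve(sis, k.reshape(shape), mode="full", axes=-1)
    return out[..., :n]


def unit_drive(
    eis: np.ndarray,
    on_weights: np.ndarray,
    off_weights: np.ndarray,
) -> np.ndarray:
    """Net subthreshold drive: weighted ON minus weighted OFF responses.

    ``eis`` is (n_pixels, n_samples); weights are non-negative, one per
    pixel.  For an OFF region a luminance-contrast increase hyperpolarizes,
    i.e. its kernel is the ON kernel inverted, hence the subtraction.
    """
    eis = np.asarray(eis, dtype=float)
    on_w = np.asarray(on_weights, dtype=float)
    off_w = np.asarray(off_weights, dtype=float)
    if eis.ndim != 2 or on_w.shape != (eis.shape[0],) or off_w.shape != (eis.shape[0],):
        raise ValueError("weights must match the pixel axis of eis")
    if np.any(on_w < 0) or np.any(off_w < 0):
        raise ValueError("weights must be non-negative")
    if not (np.any(on_w > 0) or np.any(off_w > 0)):
        raise ValueError("at least one region must be non-empty")
    return on_w @ eis - off_w @ eis
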