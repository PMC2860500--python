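"""Synthetic multiunit population: linear-nonlinear-Poisson responses to a
trial schedule.

Each unit is a simple-cell-like multiunit with non-negative ON and OFF
weights over the four tiles of the miniature image.  Its drive is the
tile contrast time course convolved with the shared biphasic kernel,
weighted ON minus OFF; the firing rate is a rectified-linear function of
the drive plus a baseline, and spike counts are Poisson per time bin.
Sixteen units mirror one 16-site laminar probe.

The kernel is rescaled so a full-contrast luminance step produces a unit
peak drive, which makes ``gain`` directly interpretable as the peak
evoked rate (spikes/s) for a preferred full-contrast transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import TemporalResponseFunction, biphasic_kernel, encode_pixel
from .stimuli import BLANK, N_TILES, TrialSchedule, contrast_of

__all__ = [
    "UnitModel",
    "PopulationConfig",
    "SpikeCountTensor",
    "make_population",
    "simulate_responses",
    "simulate_white_noise_unit",
]


@dataclass(frozen=True)
class UnitModel:
    """One synthetic multiunit: tile weights and rate-mapping parameters."""

    on_weights: np.ndarray      # (4,) non-negative
    off_weights: np.ndarray     # (4,) non-negative
    gain: float                 # spikes/s per unit drive
    baseline_rate: float        # spikes/s
    latency_ms: float = 25.0

    def __post_init__(self):
        on = np.asarray(self.on_weights, dtype=float)
        off = np.asarray(self.off_weights, dtype=float)
        object.__setattr__(self, "on_weights", on)
        object.__setattr__(self, "off_weights", off)
        if self.gain < 0 or self.baseline_rate < 0:
            raise ValueError("gain and baseline_rate must be non-negative")
        if np.any(on < 0) or np.any(off < 0):
            raise ValueError("tile weights must be non-negative")
        if not (np.any(on > 0) or np.any(off > 0)):
            raise ValueError("a unit needs at least one non-zero weight")

    @property
    def signed_weights(self) -> np.ndarray:
        return self.on_weights - self.off_weights


@dataclass
class PopulationConfig:
    """Reproducible description of a synthetic population.

    Gains and baselines are drawn uniformly from the stated ranges;
    defaults give peak evoked multiunit rates of a few tens of spikes/s
    over a low-baseline background, the order of magnitude seen in early
    visual cortex.
    """

    n_units: int = 16
    seed: int | None = 0
    gain_range: tuple[float, float] = (20.0, 60.0)
    baseline_range: tuple[float, float] = (2.0, 10.0)
    latency_ms: float = 25.0
    noise: bool = True
    kernel_params: dict = field(default_factory=dict)

    def make_kernel(self) -> TemporalResponseFunction:
        return biphasic_kernel(**self.kernel_params)


def make_population(
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> list[UnitModel]:
    """Draw a heterogeneous population of units; deterministic under seed.

    Tile weights are signed uniform draws with small magnitudes zeroed
    (sparse receptive fields); coverage of all four tiles across the
    population is enforced so every pixel of the miniature image is
    represented in the code.
    """
    if config.n_units < 1:
        raise ValueError("n_units must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    signed = rng.uniform(-1.0, 1.0, size=(config.n_units, N_TILES))
    signed[np.abs(signed) < 0.15] = 0.0
    for i in range(config.n_units):
        if not np.any(signed[i]):
            signed[i, rng.integers(N_TILES)] = rng.choice([-1.0, 1.0])
    # guarantee every tile drives at least one unit
    for tile in range(N_TILES):
        if not np.any(signed[:, tile]):
            signed[tile % config.n_units, tile] = rng.choice([-1.0, 1.0])
    gains = rng.uniform(*config.gain_range, size=config.n_units)
    baselines = rng.uniform(*config.baseline_range, size=config.n_units)
    if np.all(gains == 0):
        import warnings

        warnings.warn("degenerate population: all gains are zero", stacklevel=2)
    return [
        UnitModel(
            on_weights=np.clip(signed[i], 0, None),
            off_weights=np.clip(-signed[i], 0, None),
            gain=float(gains[i]),
            baseline_rate=float(baselines[i]),
            latency_ms=config.latency_ms,
        )
        for i in range(config.n_units)
    ]


@dataclass
class SpikeCountTensor:
    """Spike counts per recording site x time bin x stimulus period.

    Bin 0 starts at the period onset (time 0 = the transition); bin edges
    are [t, t + bin_ms).  Counts are integers under Poisson noise and
    real-valued expectations in noiseless mode.
    """

    counts: np.ndarray      # (n_sites, n_bins, n_periods)
    bin_ms: float

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (n_sites, n_bins, n_periods)")
        if np.any(c < 0):
            raise ValueError("spike counts must be non-negative")
        self.counts = c

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_ms

    def rates(self) -> np.ndarray:
        """Counts converted to firing rates in spikes/s."""
        return self.counts / (self.bin_ms / 1000.0)

    def to_long_frame(self) -> pd.DataFrame:
        sites, bins, periods = np.meshgrid(
            np.arange(self.n_sites),
            np.arange(self.n_bins),
            np.arange(self.n_periods),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "site": sites.ravel(),
                "period": periods.ravel(),
                "bin": bins.ravel(),
                "count": self.counts.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def _schedule_contrast_timecourse(
    schedule: TrialSchedule, dt_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tile contrast signal (4, n_samples) over the whole session, plus the
    per-period starting sample index."""
    starts = []
    segments = []
    t = 0
    for p in schedule.periods:
        n = int(round(p.duration_ms / dt_ms))
        starts.append(t)
        c = contrast_of(p.pattern_id) if p.pattern_id != BLANK else np.zeros(N_TILES)
        segments.append(np.repeat(c[:, None], n, axis=1))
        t += n
    return np.concatenate(segments, axis=1), np.asarray(starts)


def simulate_responses(
    schedule: TrialSchedule,
    units: list[UnitModel],
    kernel: TemporalResponseFunction | None = None,
    bin_ms: float = 10.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
    dt_ms: float = 1.0,
) -> SpikeCountTensor:
    """Simulate the population's spike-count tensor for a schedule.

    Per unit, rate(t) = baseline + gain * max(0, drive(t - latency)), with
    the drive computed by causal convolution of the tile contrast signal
    (zero-padded history, i.e. gray screen before the session).  Counts
    are Poisson per bin, independent across bins and sites; in noiseless
    mode the tensor holds the exact expected counts.
    """
    if not 1.0 <= bin_ms <= 50.0:
        raise ValueError("bin_ms must lie in [1, 50] ms")
    if kernel is None:
        kernel = biphasic_kernel(frame_ms=dt_ms)
    elif kernel.frame_ms != dt_ms:
        kernel = kernel.resampled(dt_ms)
    if rng is None:
        rng = np.random.default_rng(seed)

    sis, starts = _schedule_contrast_timecourse(schedule, dt_ms)
    # unit step drive peak -> 1, so gain is the peak rate of a preferred
    # full-contrast transition
    step_peak = np.abs(kernel.cumulative).max()
    k = TemporalResponseFunction(kernel.kernel / step_peak, kernel.frame_ms)
    eis = encode_pixel(sis, k)                     # (4, T)

    n_bins = int(schedule.periods[0].duration_ms // bin_ms)
    samples_per_bin = int(round(bin_ms / dt_ms))
    n_periods = len(schedule.periods)
    expected = np.empty((len(units), n_bins, n_periods))
    bin_sec = bin_ms / 1000.0
    for i, u in enumerate(units):
        drive = u.signed_weights @ eis
        shift = int(round(u.latency_ms / dt_ms))
        if shift:
            drive = np.concatenate([np.zeros(shift), drive[:-shift]])
        rate = u.baseline_rate + u.gain * np.clip(drive, 0.0, None)
        for j, s in enumerate(starts):
            seg = rate[s : s + n_bins * samples_per_bin]
            expected[i, :, j] = seg.reshape(n_bins, samples_per_bin).mean(axis=1) * bin_sec
    if noiseless:
        counts = expected
    else:
        counts = rng.poisson(expected)
    return SpikeCountTensor(counts=counts, bin_ms=bin_ms)


def simulate_white_noise_unit(
    kernel: TemporalResponseFunction,
    n_frames: int,
    n_pixels: int = 256,
    on_pixels: np.ndarray | None = None,
    off_pixels: np.ndarray | None = None,
    gain: float = 30.0,
    baseline_rate: float = 2.0,
    contrast_sd: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """White-noise mapping experiment for one LNP unit with a known kernel.

    Returns ``(stimulus, counts)``: zero-mean Gaussian contrast frames of
    shape (n_frames, n_pixels) at the kernel's frame resolution, and the
    unit's Poisson spike counts per frame.  Ground truth for
    reverse-correlation recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if on_pixels is None:
        on_pixels = np.arange(n_pixels // 2)
    if off_pixels is None:
        off_pixels = np.arange(n_pixels // 2, n_pixels)
    stim = rng.normal(0.0, contrast_sd, size=(n_frames, n_pixels))
    w = np.zeros(n_pixels)
    w[np.asarray(on_pixels, dtype=int)] = 1.0
    w[np.asarray(off_pixels, dtype=int)] = -1.0
    w /= np.linalg.norm(w)
    proj = stim @ w
    drive = np.convolve(proj, kernel.kernel)[: n_frames]
    # unit-variance drive: gain is the rate swing per drive s.d.
    drive /= contrast_sd * np.linalg.norm(kernel.kernel)
    rate = baseline_rate + gain * np.clip(drive, 0.0, None)
    counts = rng.poisson(rate * kernel.frame_ms / 1000.0)
    return stim, counts
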