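"""End-to-end orchestration: simulate -> dictionary -> decode -> information
-> orientation, with reproducible seeding and delimited-text outputs.

A run is fully described by a :class:`RunConfig`; identical configs (and
seeds) produce byte-identical output tables.  All stage outputs are plain
CSV; the run report is JSON with every headline number traceable to one
of the emitted tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoder import DictionaryDecoder, crossover_time, window_split_consistency
from .info import information_trace
from .kernels import biphasic_kernel
from .orientation import model_orientation_shift
from .population import PopulationConfig, SpikeCountTensor, make_population, simulate_responses
from .stimuli import TrialSchedule, build_session, pattern_matrix, transitions

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_counts", "default_config"]

log = logging.getLogger("popdecode")


@dataclass
class StimulusConfig:
    n_repeats: int = 10
    duration_ms: float = 250.0


@dataclass
class AnalysisConfig:
    bin_ms: float = 10.0
    dictionary_window: tuple[float, float] = (0.0, 250.0)
    n_shuffles: int = 20
    crossover_k: int = 3
    # early window brackets the population rate peak (kernel peak + latency);
    # late window starts after the difference -> current handover
    early_ms: tuple[float, float] = (60.0, 150.0)
    late_ms: tuple[float, float] = (180.0, 250.0)


@dataclass
class OrientationConfig:
    n_pixels: int = 64
    tile_px: int = 8
    window_ms: tuple[float, float] = (25.0, 90.0)
    readout: str = "complex"
    noisy_units: int = 17
    gain: float = 40.0
    baseline_rate: float = 2.0


@dataclass
class RunConfig:
    seed: int = 0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    save_tensors: bool = True
    figures: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        for key, klass in (
            ("stimulus", StimulusConfig),
            ("population", PopulationConfig),
            ("analysis", AnalysisConfig),
            ("orientation", OrientationConfig),
        ):
            if key in raw and raw[key] is not None:
                section = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
                }
                setattr(cfg, key, klass(**section))
        for flag in ("save_tensors", "figures"):
            if flag in raw:
                setattr(cfg, flag, bool(raw[flag]))
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def default_config() -> RunConfig:
    return RunConfig()


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    n_relay_transitions: int
    n_permutations: int
    n_significant_sites: int
    crossover_time_ms: float | None
    early_corr_previous: float
    early_corr_current: float
    early_corr_difference: float
    late_corr_previous: float
    late_corr_current: float
    late_corr_difference: float
    early_info_current_bits: float
    early_info_previous_bits: float
    late_info_current_bits: float
    late_info_previous_bits: float
    window_split_pearson: float
    orientation_shift_deg: float
    orientation_shift_noisy_deg: float
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _window_mean(values: np.ndarray, time_ms: np.ndarray, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (time_ms >= lo) & (time_ms < hi)
    return float(values[mask].mean())


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute every analysis stage on synthetic data and write all tables.

    Stage failures abort with a stage-identified logged error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, 6)
    log.info(
        "run config_hash=%s seed=%d version=%s numpy=%s",
        config.hash(), config.seed, __version__, np.__version__,
    )
    (out / "config.yaml").write_text(config.to_yaml())
    timings: dict[str, float] = {}
    stage = "stimulus"
    try:
        t0 = time.perf_counter()
        session = build_session(config.stimulus.n_repeats, seed=seeds[0],
                                duration_ms=config.stimulus.duration_ms)
        session.relay.to_csv(out / "schedule_relay.csv")
        session.dictionary.to_csv(out / "schedule_dictionary.csv")
        patterns = pattern_matrix()
        timings[stage] = time.perf_counter() - t0

        stage = "simulate"
        t0 = time.perf_counter()
        pop_cfg = config.population
        units = make_population(pop_cfg, rng=np.random.default_rng(seeds[1]))
        kernel = pop_cfg.make_kernel()
        noiseless = not pop_cfg.noise
        relay_tensor = simulate_responses(
            session.relay, units, kernel, bin_ms=config.analysis.bin_ms,
            seed=seeds[2], noiseless=noiseless,
        )
        dict_tensor = simulate_responses(
            session.dictionary, units, kernel, bin_ms=config.analysis.bin_ms,
            seed=seeds[3], noiseless=noiseless,
        )
        if config.save_tensors:
            relay_tensor.to_csv(out / "counts_relay.csv")
            dict_tensor.to_csv(out / "counts_dictionary.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "dictionary"
        t0 = time.perf_counter()
        decoder = DictionaryDecoder(
            window=config.analysis.dictionary_window, crossover_k=config.analysis.crossover_k
        ).fit(dict_tensor, session.dictionary)
        decoder.dictionary_.to_csv(out / "dictionary.csv")
        mask = decoder.significance_mask_
        timings[stage] = time.perf_counter() - t0

        stage = "decode"
        t0 = time.perf_counter()
        trace = decoder.trace(relay_tensor, session.relay)
        trace.to_csv(out / "trace_relay.csv")
        crossover = crossover_time(trace, k=config.analysis.crossover_k)
        trace_a, trace_b, split_r = window_split_consistency(
            relay_tensor, session.relay, dict_tensor, session.dictionary, patterns
        )
        trace_a.to_csv(out / "trace_window_0_90.csv")
        trace_b.to_csv(out / "trace_window_90_250.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "information"
        t0 = time.perf_counter()
        sites = np.flatnonzero(mask) if mask.any() else np.arange(relay_tensor.n_sites)
        info = information_trace(
            relay_tensor, session.relay, sites=sites,
            n_shuffles=config.analysis.n_shuffles, rng=np.random.default_rng(seeds[4]),
        )
        info.to_csv(out / "info_relay.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "orientation"
        t0 = time.perf_counter()
        ocfg = config.orientation
        from .stimuli import orientation_test_stimuli

        stimuli = orientation_test_stimuli(n_pixels=ocfg.n_pixels, tile_px=ocfg.tile_px)
        shift = model_orientation_shift(
            kernel, stimuli, window_ms=ocfg.window_ms, readout=ocfg.readout,
            gain=ocfg.gain, baseline_rate=ocfg.baseline_rate,
        )
        noisy_orients = np.arange(ocfg.noisy_units) * (180.0 / ocfg.noisy_units)
        shift_noisy, shifts, prefs = model_orientation_shift(
            kernel, stimuli, unit_orientations=noisy_orients,
            window_ms=ocfg.window_ms, readout=ocfg.readout,
            gain=ocfg.gain, baseline_rate=ocfg.baseline_rate,
            rng=np.random.default_rng(seeds[5]), return_details=True,
        )
        pd.DataFrame(
            {
                "unit_orientation_deg": noisy_orients,
                "pref_blank_deg": [p[0] for p in prefs],
                "pref_checker_deg": [p[1] for p in prefs],
                "shift_deg": shifts,
            }
        ).to_csv(out / "orientation_shifts.csv", index=False)
        timings[stage] = time.perf_counter() - t0
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        raise

    t = trace.time_ms
    early, late = config.analysis.early_ms, config.analysis.late_ms
    report = RunReport(
        seed=config.seed,
        config_hash=config.hash(),
        version=__version__,
        n_relay_transitions=len(transitions(session.relay)),
        n_permutations=session.n_permutations,
        n_significant_sites=int(mask.sum()),
        crossover_time_ms=crossover,
        early_corr_previous=_window_mean(trace.mean_previous, t, early),
        early_corr_current=_window_mean(trace.mean_current, t, early),
        early_corr_difference=_window_mean(trace.mean_difference, t, early),
        late_corr_previous=_window_mean(trace.mean_previous, t, late),
        late_corr_current=_window_mean(trace.mean_current, t, late),
        late_corr_difference=_window_mean(trace.mean_difference, t, late),
        early_info_current_bits=_window_mean(info.info_current_bits, info.time_ms, early),
        early_info_previous_bits=_window_mean(info.info_previous_bits, info.time_ms, early),
        late_info_current_bits=_window_mean(info.info_current_bits, info.time_ms, late),
        late_info_previous_bits=_window_mean(info.info_previous_bits, info.time_ms, late),
        window_split_pearson=split_r,
        orientation_shift_deg=shift,
        orientation_shift_noisy_deg=shift_noisy,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
    )
    (out / "report.json").write_text(report.to_json())
    if config.figures:
        _plot_run(out, trace, info)
    return report


def _plot_run(out: Path, trace, info) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    ax = axes[0]
    ax.plot(trace.time_ms, trace.mean_previous, "--", label="previous")
    ax.plot(trace.time_ms, trace.mean_current, "-", label="current")
    ax.plot(trace.time_ms, trace.mean_difference, "r--", label="difference")
    ax.set(xlabel="time after transition (ms)", ylabel="correlation")
    ax.legend()
    ax = axes[1]
    ax.plot(info.time_ms, info.info_current_bits, "-", label="current")
    ax.plot(info.time_ms, info.info_previous_bits, "--", label="previous")
    ax.set(xlabel="time after transition (ms)", ylabel="information (bits)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "traces.png", dpi=120)
    plt.close(fig)


def load_counts(path: str | Path, schedule: TrialSchedule) -> SpikeCountTensor:
    """Load a long-format (site, period, bin, count) table as a tensor.

    The file must cover every schedule period for every site; unknown
    period ids, missing entries, and negative counts are rejected with the
    offenders named.
    """
    frame = pd.read_csv(path)
    required = {"site", "period", "bin", "count"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    if (frame["count"] < 0).any():
        bad = frame.loc[frame["count"] < 0].head()
        raise ValueError(f"negative spike counts, e.g.:\n{bad}")
    known = {p.index for p in schedule.periods}
    unknown = sorted(set(frame["period"]) - known)
    if unknown:
        raise ValueError(f"unknown period ids not in schedule: {unknown[:10]}")
    sites = np.sort(frame["site"].unique())
    bins = np.sort(frame["bin"].unique())
    n_sites, n_bins, n_periods = len(sites), len(bins), len(known)
    if len(frame) != n_sites * n_bins * n_periods:
        have = frame.groupby("site")["period"].nunique()
        short = have[have < n_periods].index.tolist()
        raise ValueError(
            f"incomplete tensor: expected {n_sites * n_bins * n_periods} rows, "
            f"got {len(frame)}; sites missing periods: {short[:10]}"
        )
    counts = np.zeros((n_sites, n_bins, n_periods))
    site_pos = {s: i for i, s in enumerate(sites)}
    bin_pos = {b: i for i, b in enumerate(bins)}
    counts[
        frame["site"].map(site_pos), frame["bin"].map(bin_pos), frame["period"].to_numpy()
    ] = frame["count"].to_numpy()
    duration = schedule.periods[0].duration_ms
    return SpikeCountTensor(counts=counts, bin_ms=duration / n_bins)
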