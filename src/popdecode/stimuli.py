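"""Stimulus construction for the pattern-transition decoding experiments.

The stimulus set is the full enumeration of 2x2 'miniature image' tile
patterns with three luminance levels per tile (black 0.01, gray 6,
white 60 Cd/m^2), i.e. 3**4 = 81 patterns.  On screen each miniature
image is tiled periodically, so all analyses operate on the 2x2 pattern
itself.  Patterns carry two views:

* ``luminance`` -- physical tile luminances in Cd/m^2;
* ``contrast`` -- the signed contrast code used by the decoder, with
  black = +1, gray = 0, white = -1.

Pattern ids are the base-3 encoding of the contrast tuple in tile order
(upper-left, upper-right, lower-left, lower-right) with digit mapping
black = 0, gray = 1, white = 2, so dictionaries built in different runs
are directly comparable.

Two presentation paradigms are generated: a *relay* paradigm (patterns
back-to-back, 250 ms each, no blanks) whose transitions are decoded, and
a *dictionary* paradigm (a 250 ms gray blank before every pattern) used
to measure each pattern's isolated population response.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BLANK",
    "LUMINANCE_LEVELS",
    "CONTRAST_LEVELS",
    "TilePattern",
    "PatternMatrix",
    "DifferencePattern",
    "StimulusPeriod",
    "TrialSchedule",
    "Transition",
    "GratingStimulus",
    "enumerate_patterns",
    "pattern_matrix",
    "normalize_vector",
    "normalize_columns",
    "difference_pattern",
    "contrast_of",
    "build_schedule",
    "build_session",
    "transitions",
    "render_checker",
    "render_grating",
    "orientation_test_stimuli",
]

#: Sentinel pattern id for a homogeneous gray blank period.
BLANK = -1

#: Tile luminances in Cd/m^2 indexed by base-3 digit (black, gray, white).
LUMINANCE_LEVELS = (0.01, 6.0, 60.0)

#: Contrast code indexed by base-3 digit: black = +1, gray = 0, white = -1.
CONTRAST_LEVELS = (1, 0, -1)

#: Stimulus period duration in ms (patterns and blanks alike).
PERIOD_MS = 250.0

N_TILES = 4
N_PATTERNS = len(LUMINANCE_LEVELS) ** N_TILES  # 81


@dataclass(frozen=True)
class TilePattern:
    """A 2x2 luminance pattern (tile order UL, UR, LL, LR)."""

    id: int
    luminance: tuple[float, float, float, float]
    contrast: tuple[int, int, int, int]


@dataclass(frozen=True)
class DifferencePattern:
    """Element-wise contrast difference between two tile patterns (B - A)."""

    values: np.ndarray     # integers in {-2, -1, 0, 1, 2}
    normalized: np.ndarray


@dataclass(frozen=True)
class PatternMatrix:
    """Contrast matrix of the full pattern set.

    ``raw`` holds the un-normalized contrast codes (P x 4); ``S`` the
    row-normalized form in which the dot product of two rows equals the
    Pearson correlation of the corresponding patterns.  The all-gray
    pattern normalizes to the zero row.
    """

    S: np.ndarray
    raw: np.ndarray
    pattern_ids: np.ndarray


def enumerate_patterns() -> list[TilePattern]:
    """Enumerate all 81 tile patterns in stable id order.

    The id is the base-3 number formed by the tile digits (UL most
    significant), digit 0 = black, 1 = gray, 2 = white; e.g. the all-gray
    pattern has id 40 (= 1111 in base 3).
    """
    patterns = []
    for digits in itertools.product(range(3), repeat=N_TILES):
        pid = int(np.polyval(digits, 3))  # base-3 value, UL most significant
        patterns.append(
            TilePattern(
                id=pid,
                luminance=tuple(LUMINANCE_LEVELS[d] for d in digits),
                contrast=tuple(CONTRAST_LEVELS[d] for d in digits),
            )
        )
    patterns.sort(key=lambda p: p.id)
    return patterns


def normalize_vector(v: np.ndarray) -> np.ndarray:
    """Center and scale a vector so dot products are Pearson correlations.

    Returns ``(v - mean(v)) / ||v - mean(v)||`` for non-constant ``v`` and
    the zero vector for constant ``v`` (a contrast-free pattern carries no
    spatial signal, so every correlation with it is 0 by convention).

    Raises
    ------
    ValueError
        If ``v`` contains non-finite values.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("normalize_vector requires finite input")
    centered = v - v.mean()
    norm = np.linalg.norm(centered)
    if norm <= 1e-12 * max(1.0, float(np.abs(v).max(initial=0.0))):
        return np.zeros_like(v)
    return centered / norm


def normalize_columns(m: np.ndarray) -> np.ndarray:
    """Column-wise :func:`normalize_vector` for a 2-D array (vectorized)."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("normalize_columns requires finite input")
    centered = m - m.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(centered, axis=0, keepdims=True)
    tol = 1e-12 * np.maximum(1.0, np.abs(m).max(axis=0, keepdims=True, initial=0.0))
    safe = np.where(norm > tol, norm, 1.0)
    out = centered / safe
    out[:, (norm <= tol)[0]] = 0.0
    return out


def pattern_matrix(patterns: list[TilePattern] | None = None) -> PatternMatrix:
    """Stack the pattern contrast codes into raw and row-normalized matrices."""
    if patterns is None:
        patterns = enumerate_patterns()
    raw = np.array([p.contrast for p in patterns], dtype=float)
    S = normalize_columns(raw.T).T
    ids = np.array([p.id for p in patterns])
    return PatternMatrix(S=S, raw=raw, pattern_ids=ids)


def difference_pattern(a: TilePattern, b: TilePattern) -> DifferencePattern:
    """Element-wise contrast difference B - A of two decoding patterns.

    Subtraction acts on the un-normalized contrast codes, so the values
    lie in {-2, -1, 0, 1, 2}; the normalized view follows the usual
    contract (zero vector for an identity transition).
    """
    values = np.asarray(b.contrast, dtype=int) - np.asarray(a.contrast, dtype=int)
    return DifferencePattern(values=values, normalized=normalize_vector(values))


def contrast_of(pattern_id: int, patterns: list[TilePattern] | None = None) -> np.ndarray:
    """Contrast 4-vector of a pattern id; a blank maps to the zero vector."""
    if pattern_id == BLANK:
        return np.zeros(N_TILES)
    if patterns is None:
        digits = []
        pid = pattern_id
        for _ in range(N_TILES):
            digits.append(pid % 3)
            pid //= 3
        return np.array([CONTRAST_LEVELS[d] for d in reversed(digits)], dtype=float)
    return np.asarray(patterns[pattern_id].contrast, dtype=float)


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusPeriod:
    index: int
    paradigm: str           # "relay" or "dictionary"
    pattern_id: int         # BLANK for a gray period
    onset_ms: float
    duration_ms: float = PERIOD_MS


@dataclass
class TrialSchedule:
    """Ordered stimulus periods of one (possibly interleaved) session.

    ``permutations`` records each fresh random ordering drawn while
    building the schedule, one per repetition block and paradigm.
    """

    periods: list[StimulusPeriod]
    seed: int | None = None
    permutations: list[np.ndarray] = field(default_factory=list)

    @property
    def n_permutations(self) -> int:
        return len(self.permutations)

    @property
    def total_duration_ms(self) -> float:
        last = self.periods[-1]
        return last.onset_ms + last.duration_ms

    def pattern_periods(self, paradigm: str | None = None) -> list[StimulusPeriod]:
        return [
            p for p in self.periods
            if p.pattern_id != BLANK and (paradigm is None or p.paradigm == paradigm)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_index": [p.index for p in self.periods],
                "paradigm": [p.paradigm for p in self.periods],
                "pattern_id": [p.pattern_id for p in self.periods],
                "onset_ms": [p.onset_ms for p in self.periods],
                "duration_ms": [p.duration_ms for p in self.periods],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSchedule":
        periods = [
            StimulusPeriod(
                index=int(r.period_index),
                paradigm=str(r.paradigm),
                pattern_id=int(r.pattern_id),
                onset_ms=float(r.onset_ms),
                duration_ms=float(r.duration_ms),
            )
            for r in frame.itertuples()
        ]
        return cls(periods=periods)

    @classmethod
    def from_csv(cls, path) -> "TrialSchedule":
        return cls.from_frame(pd.read_csv(path))


def _relay_block(perm, start_index, onset_ms, duration_ms):
    """One relay repetition: a gray adaptation period, then all patterns
    back-to-back in permuted order."""
    periods = [StimulusPeriod(start_index, "relay", BLANK, onset_ms, duration_ms)]
    t = onset_ms + duration_ms
    for k, pid in enumerate(perm, start=start_index + 1):
        periods.append(StimulusPeriod(k, "relay", int(pid), t, duration_ms))
        t += duration_ms
    return periods, t


def _dictionary_block(perm, start_index, onset_ms, duration_ms):
    """One dictionary repetition: a 250 ms gray blank before every pattern."""
    periods = []
    t = onset_ms
    k = start_index
    for pid in perm:
        periods.append(StimulusPeriod(k, "dictionary", BLANK, t, duration_ms))
        t += duration_ms
        periods.append(StimulusPeriod(k + 1, "dictionary", int(pid), t, duration_ms))
        t += duration_ms
        k += 2
    return periods, t


def build_schedule(
    paradigm: str,
    n_repeats: int = 10,
    seed: int | None = None,
    duration_ms: float = PERIOD_MS,
    rng: np.random.Generator | None = None,
) -> TrialSchedule:
    """Build a relay or dictionary schedule of ``n_repeats`` repetition blocks.

    Every block uses a fresh random permutation of all 81 patterns.  Relay
    blocks prepend one gray adaptation period, so the first pattern of a
    block has a well-defined (gray) previous stimulus; dictionary blocks
    interleave a gray blank before every pattern.
    """
    if paradigm not in ("relay", "dictionary"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    periods: list[StimulusPeriod] = []
    perms: list[np.ndarray] = []
    onset = 0.0
    for _ in range(n_repeats):
        perm = rng.permutation(N_PATTERNS)
        perms.append(perm)
        builder = _relay_block if paradigm == "relay" else _dictionary_block
        block, onset = builder(perm, len(periods), onset, duration_ms)
        periods.extend(block)
    return TrialSchedule(periods=periods, seed=seed, permutations=perms)


@dataclass
class Session:
    """A recording session: interleaved relay and dictionary repetitions.

    The two paradigms are stored as separate schedules (they are analysed
    separately), but the permutations are drawn alternately from one
    generator, mirroring the interleaved presentation; 10 repetitions of
    both paradigms therefore consume 20 distinct permutations.
    """

    relay: TrialSchedule
    dictionary: TrialSchedule
    seed: int | None = None

    @property
    def n_permutations(self) -> int:
        return self.relay.n_permutations + self.dictionary.n_permutations


def build_session(
    n_repeats: int = 10,
    seed: int | None = None,
    duration_ms: float = PERIOD_MS,
) -> Session:
    rng = np.random.default_rng(seed)
    relay_periods: list[StimulusPeriod] = []
    dict_periods: list[StimulusPeriod] = []
    relay_perms, dict_perms = [], []
    onset_r = onset_d = 0.0
    for _ in range(n_repeats):
        perm_r = rng.permutation(N_PATTERNS)
        perm_d = rng.permutation(N_PATTERNS)
        relay_perms.append(perm_r)
        dict_perms.append(perm_d)
        block, onset_r = _relay_block(perm_r, len(relay_periods), onset_r, duration_ms)
        relay_periods.extend(block)
        block, onset_d = _dictionary_block(perm_d, len(dict_periods), onset_d, duration_ms)
        dict_periods.extend(block)
    return Session(
        relay=TrialSchedule(relay_periods, seed=seed, permutations=relay_perms),
        dictionary=TrialSchedule(dict_periods, seed=seed, permutations=dict_perms),
        seed=seed,
    )


@dataclass(frozen=True)
class Transition:
    period_index: int
    previous_id: int   # BLANK for gray
    current_id: int


def transitions(schedule: TrialSchedule) -> list[Transition]:
    """Every pattern period counts as one transition from its predecessor.

    The predecessor of the first pattern in a relay block is the gray
    adaptation period (pattern id BLANK, contrast zero).
    """
    out = []
    for i, p in enumerate(schedule.periods):
        if p.pattern_id == BLANK:
            continue
        prev = schedule.periods[i - 1].pattern_id if i > 0 else BLANK
        out.append(Transition(p.index, prev, p.pattern_id))
    return out


# ---------------------------------------------------------------------------
# Orientation-test stimuli
# ---------------------------------------------------------------------------

#: Checker tile luminances (Cd/m^2), rows x columns of the 2x2 cell.
CHECKER_LUMINANCES = ((0.0, 10.0), (10.0, 60.0))
GRATING_LUMINANCES = (5.0, 35.0)
ORIENTATION_BACKGROUND = 20.0
N_ORIENTATIONS = 16


@dataclass(frozen=True)
class GratingStimulus:
    """A stationary square-wave grating and its preceding 250 ms stimulus."""

    orientation_deg: float
    preceding: str                     # "blank" or "checker"
    luminances: tuple[float, float] = GRATING_LUMINANCES
    background: float = ORIENTATION_BACKGROUND


def _rotated_tile_coords(n_pixels: int, tile_px: int, orientation_deg: float):
    """Rotated-frame tile parities for rendering; orientation 90 deg gives
    vertical stripes (luminance varying along x).

    Tile boundaries follow the sign of a cosine in the rotated frame, so
    the rendered patterns are symmetric under reflection about the stripe
    axes and under 180 deg rotation about the image center (the rotation
    pivot).  This keeps the transition geometry exactly equivalent at
    every orientation.
    """
    c = np.arange(n_pixels) - (n_pixels - 1) / 2.0
    x = c[None, :]
    y = c[:, None]
    phi = np.deg2rad(orientation_deg - 90.0)
    u = x * np.cos(phi) + y * np.sin(phi)
    v = -x * np.sin(phi) + y * np.cos(phi)
    col = np.where(np.cos(np.pi * u / tile_px) >= 0, 0, 1)
    row = np.where(np.cos(np.pi * v / tile_px) >= 0, 0, 1)
    return col, row


def render_grating(orientation_deg: float, n_pixels: int = 64, tile_px: int = 8) -> np.ndarray:
    """Render the square-wave grating (luminance image, Cd/m^2)."""
    col, _ = _rotated_tile_coords(n_pixels, tile_px, orientation_deg)
    lo, hi = GRATING_LUMINANCES
    return np.where(col == 0, lo, hi).astype(float)


def render_checker(orientation_deg: float, n_pixels: int = 64, tile_px: int = 8) -> np.ndarray:
    """Render the fixed (0, 10, 10, 60 Cd/m^2) checker pattern, rotated with
    the grating so the transition geometry is identical at every orientation."""
    col, row = _rotated_tile_coords(n_pixels, tile_px, orientation_deg)
    lum = np.asarray(CHECKER_LUMINANCES)
    return lum[row, col].astype(float)


def orientation_test_stimuli(
    n_pixels: int = 64,
    tile_px: int = 8,
    n_orientations: int = N_ORIENTATIONS,
) -> list[dict]:
    """Blank->grating and checker->grating transitions at all 16 orientations.

    Each entry carries the rendered luminance images (blank, checker,
    grating) plus the analytic difference image of the pattern->grating
    transition (grating minus checker), whose oriented energy is orthogonal
    to the grating.
    """
    step = 360.0 / n_orientations
    out = []
    for k in range(n_orientations):
        theta = k * step
        grating = render_grating(theta, n_pixels, tile_px)
        checker = render_checker(theta, n_pixels, tile_px)
        blank = np.full_like(grating, ORIENTATION_BACKGROUND)
        out.append(
            {
                "orientation_deg": theta,
                "blank": blank,
                "checker": checker,
                "grating": grating,
                "difference": grating - checker,
                "stimuli": (
                    GratingStimulus(theta, "blank"),
                    GratingStimulus(theta, "checker"),
                ),
            }
        )
    return out
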