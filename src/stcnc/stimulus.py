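"""Stimulus protocols: white-noise checkerboard, full-field flash, flashing spot.

All protocols are deterministic functions of an explicit seed so that a
stimulus can be regenerated bit-identically from its configuration instead
of being stored.  Internally the checkerboard movie is kept as *contrast*
(deviation from mean luminance, cd/m^2); absolute luminance appears only at
I/O boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "StimulusConfig",
    "FrameSequence",
    "FlashProtocol",
    "SpotProtocol",
    "generate_white_noise",
    "generate_flash_protocol",
    "generate_spot_protocol",
    "flash_frame_sequence",
    "spot_frame_sequence",
    "truncated_gaussian_sd",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and luminance statistics of the checkerboard stimulus.

    Defaults are Gaussian white noise at mean 2 cd/m^2, s.d. 0.78 cd/m^2,
    truncated to the displayable range [0, 4] cd/m^2, refreshed every 33 ms
    on a grid of 100 um checkers.
    """

    grid_rows: int = 16
    grid_cols: int = 16
    checker_size_um: float = 100.0
    frame_interval_ms: float = 33.0
    mean_luminance: float = 2.0
    luminance_sd: float = 0.78
    luminance_range: tuple[float, float] = (0.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.luminance_range
        if not (lo <= self.mean_luminance <= hi):
            raise ValueError("mean_luminance must lie inside luminance_range")
        if self.luminance_sd <= 0:
            raise ValueError("luminance_sd must be positive")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one checker")

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval_ms / 1000.0

    @property
    def n_checkers(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def contrast_bounds(self) -> tuple[float, float]:
        """Contrast range implied by the luminance range."""
        lo, hi = self.luminance_range
        return (lo - self.mean_luminance, hi - self.mean_luminance)

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["luminance_range"] = list(self.luminance_range)
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusConfig":
        doc = json.loads(Path(path).read_text())
        doc["luminance_range"] = tuple(doc["luminance_range"])
        return cls(**doc)


@dataclass
class FrameSequence:
    """A white-noise movie as contrast values on the checker grid.

    ``frames`` has shape (T, rows, cols); spatial indexing is row-major and
    0-based with checker (0, 0) at the top-left.  ``frame_times`` are onset
    times in seconds, uniformly spaced at the frame interval.
    """

    config: StimulusConfig
    frames: np.ndarray
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, rows, cols) array")
        if self.frame_times is None:
            self.frame_times = (
                np.arange(self.frames.shape[0]) * self.config.frame_interval_s
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def luminance(self) -> np.ndarray:
        return self.frames + self.config.mean_luminance

    def save_raw(self, path: str | Path) -> None:
        """Flat binary of float32 contrasts, frame-major then row-major,
        with a JSON sidecar holding shape and units."""
        path = Path(path)
        self.frames.astype(np.float32).tofile(path)
        sidecar = {
            "shape": list(self.frames.shape),
            "dtype": "float32",
            "units": "contrast_cd_per_m2",
            "layout": "frame_major_then_row_major",
            "config": json.loads(json.dumps(asdict(self.config), default=list)),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load_raw(cls, path: str | Path) -> "FrameSequence":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg = sidecar["config"]
        cfg["luminance_range"] = tuple(cfg["luminance_range"])
        config = StimulusConfig(**cfg)
        frames = np.fromfile(path, dtype=np.float32).reshape(sidecar["shape"])
        return cls(config=config, frames=frames.astype(np.float64))


@dataclass
class FlashProtocol:
    """Repeating full-field cycle: 2 s light OFF (0 cd/m^2) then 2 s ON (4 cd/m^2)."""

    n_cycles: int
    off_duration_s: float = 2.0
    on_duration_s: float = 2.0
    off_luminance: float = 0.0
    on_luminance: float = 4.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.off_duration_s <= 0 or self.on_duration_s <= 0:
            raise ValueError("phase durations must be positive")

    @property
    def cycle_duration_s(self) -> float:
        return self.off_duration_s + self.on_duration_s

    @property
    def off_onsets(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_duration_s

    @property
    def on_onsets(self) -> np.ndarray:
        return self.off_onsets + self.off_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_duration_s


@dataclass
class SpotProtocol:
    """Randomized single-checker flashes on a mean-luminance background.

    ``events`` is a structured record of (time_s, row, col, polarity) where
    polarity is +1 for a bright (4 cd/m^2) and -1 for a dark (0 cd/m^2) spot.
    One spot is shown per second.
    """

    events: np.ndarray  # structured: time_s, row, col, polarity
    repeats_per_location_per_polarity: int
    inter_event_interval_s: float = 1.0
    seed: int = 0

    EVENT_DTYPE = np.dtype(
        [("time_s", "f8"), ("row", "i8"), ("col", "i8"), ("polarity", "i8")]
    )


def generate_white_noise(config: StimulusConfig, n_frames: int) -> FrameSequence:
    """Draw a Gaussian white-noise checkerboard movie.

    Each checker's luminance on each frame is an independent draw from a
    Gaussian (``mean_luminance``, ``luminance_sd``) truncated to
    ``luminance_range``; truncation is by the exact truncated-normal law
    (no clipping, so no probability mass accumulates at the bounds).
    Identical (config, seed, n_frames) yields bit-identical output.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.luminance_range
    a = lo - config.mean_luminance
    b = hi - config.mean_luminance
    size = n_frames * config.grid_rows * config.grid_cols
    out = rng.normal(0.0, config.luminance_sd, size=size)
    bad = (out < a) | (out > b)
    while bad.any():  # redraw out-of-range values (exact truncated normal)
        out[bad] = rng.normal(0.0, config.luminance_sd, size=int(bad.sum()))
        bad = (out < a) | (out > b)
    frames = out.reshape(n_frames, config.grid_rows, config.grid_cols)
    return FrameSequence(config=config, frames=frames)


def truncated_gaussian_sd(config: StimulusConfig) -> float:
    """Standard deviation of the emitted (truncated) luminance distribution.

    Slightly below ``luminance_sd`` because of the truncation; for the
    defaults (sd 0.78 truncated at +/-2 cd/m^2) it is about 0.749 cd/m^2.
    """
    a = (config.luminance_range[0] - config.mean_luminance) / config.luminance_sd
    b = (config.luminance_range[1] - config.mean_luminance) / config.luminance_sd
    return float(stats.truncnorm.std(a, b, loc=0.0, scale=config.luminance_sd))


def generate_flash_protocol(n_cycles: int) -> FlashProtocol:
    """Full-field flash protocol: per cycle, 2 s OFF then 2 s ON."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return FlashProtocol(n_cycles=n_cycles)


def generate_spot_protocol(
    config: StimulusConfig,
    locations: list[tuple[int, int]],
    repeats: int = 20,
    seed: int = 0,
) -> SpotProtocol:
    """Build a randomized spot sequence covering every (location, polarity)
    pair ``repeats`` times, one event per second."""
    if not locations:
        raise ValueError("locations must be non-empty")
    for r, c in locations:
        if not (0 <= r < config.grid_rows and 0 <= c < config.grid_cols):
            raise ValueError(f"location {(r, c)} outside the grid")
    if repeats < 20:
        warnings.warn(
            "fewer than 20 repeats per location/polarity gives noisy spot PSTHs",
            stacklevel=2,
        )
    combos = [
        (r, c, pol) for (r, c) in locations for pol in (+1, -1) for _ in range(repeats)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    events = np.empty(len(combos), dtype=SpotProtocol.EVENT_DTYPE)
    for i, j in enumerate(order):
        r, c, pol = combos[j]
        events[i] = (float(i), r, c, pol)
    return SpotProtocol(
        events=events, repeats_per_location_per_polarity=repeats, seed=seed
    )


def flash_frame_sequence(protocol: FlashProtocol, config: StimulusConfig) -> FrameSequence:
    """Render a full-field flash protocol on the frame clock so the same
    LN simulator that consumes white noise can be driven by it."""
    dt = config.frame_interval_s
    T = int(round(protocol.total_duration_s / dt))
    times = np.arange(T) * dt
    phase = np.mod(times, protocol.cycle_duration_s)
    lum = np.where(phase < protocol.off_duration_s, protocol.off_luminance,
                   protocol.on_luminance)
    frames = np.repeat(
        (lum - config.mean_luminance)[:, None, None],
        config.grid_rows * config.grid_cols, axis=1,
    ).reshape(T, config.grid_rows, config.grid_cols)
    return FrameSequence(config=config, frames=frames)


def spot_frame_sequence(
    protocol: SpotProtocol,
    config: StimulusConfig,
    bright_luminance: float = 4.0,
    dark_luminance: float = 0.0,
) -> FrameSequence:
    """Render a spot protocol: mean-luminance background with the flashed
    checker held at the spot luminance until the next event."""
    dt = config.frame_interval_s
    iei = protocol.inter_event_interval_s
    T = int(round((protocol.events["time_s"][-1] + iei) / dt))
    frames = np.zeros((T, config.grid_rows, config.grid_cols))
    for ev in protocol.events:
        i0 = int(round(ev["time_s"] / dt))
        i1 = int(round((ev["time_s"] + iei) / dt))
        lum = bright_luminance if ev["polarity"] > 0 else dark_luminance
        frames[i0:i1, ev["row"], ev["col"]] = lum - config.mean_luminance
    return FrameSequence(config=config, frames=frames)
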