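"""Ground-truth LN-Poisson model cells and their simulated spike trains.

Each synthetic cell is a linear-nonlinear cascade: a space-time separable
linear filter (elliptical Gaussian center x biphasic temporal kernel)
followed by a static nonlinearity, driving an inhomogeneous Poisson spike
count per stimulus frame.  Rectifying nonlinearities make ON or OFF cells;
even-symmetric ones make ON-OFF cells whose spike-triggered average cancels
— the regime the non-centered covariance analysis is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gamma as gamma_fn

from .ensemble import SpikeTrain
from .stimulus import FrameSequence, StimulusConfig, truncated_gaussian_sd

__all__ = [
    "GroundTruthFilter",
    "NonlinearitySpec",
    "SyntheticCell",
    "biphasic_kernel",
    "make_cell",
    "simulate_spikes",
    "make_population",
    "calibrate_gain",
]

LABELS = ("ON", "OFF", "ON_OFF")


def biphasic_kernel(
    f: int,
    peak_frames: float = 3.0,
    trough_frames: float = 6.0,
    trough_weight: float = 0.6,
    order: float = 4.0,
) -> np.ndarray:
    """Biphasic temporal kernel over ``f`` frames of history.

    Index 0 is the oldest frame, index f-1 the frame immediately preceding
    the spike.  The kernel is a difference of two gamma-like lobes with the
    dominant (positive) lobe peaking ``peak_frames`` before the spike —
    most real cells show such biphasic structure.  Normalized to unit
    Euclidean norm.
    """
    tau = (f - 0.5) - np.arange(f)  # frames before the spike, midpoints
    def lobe(t_peak: float) -> np.ndarray:
        z = tau / t_peak
        return z**order * np.exp(order * (1.0 - z))
    k = lobe(peak_frames) - trough_weight * lobe(trough_frames)
    return k / np.linalg.norm(k)


@dataclass
class GroundTruthFilter:
    """Space-time separable linear filter sampled on the checker grid.

    ``spatial`` is a (rows, cols) elliptical-Gaussian profile; ``temporal``
    is the f-frame kernel (oldest frame first).  ``vector`` is the
    linearized, unit-norm M-vector in the same frame-major-then-row-major
    layout used by the spike-triggered ensemble.
    """

    spatial: np.ndarray
    temporal: np.ndarray
    config: StimulusConfig
    center_um: tuple[float, float] = (0.0, 0.0)  # (x, y) = (col, row) axis, um
    sigma_um: tuple[float, float] = (70.0, 70.0)
    theta: float = 0.0
    polarity: int = +1

    @property
    def f(self) -> int:
        return len(self.temporal)

    @property
    def vector(self) -> np.ndarray:
        v = np.einsum("t,rc->trc", self.temporal, self.spatial).ravel()
        return v / np.linalg.norm(v)

    @property
    def center_checker(self) -> tuple[int, int]:
        """Grid (row, col) of the checker containing the spatial center."""
        h, k = self.center_um
        col = int(h // self.config.checker_size_um)
        row = int(k // self.config.checker_size_um)
        return (row, col)

    def windowed_vector(
        self, center: tuple[int, int], spatial: tuple[int, int] = (5, 5)
    ) -> np.ndarray:
        """Unit-norm filter restricted to a spatial window (zero-padded at
        edges), for comparison against windowed estimates."""
        rows, cols = self.spatial.shape
        wr, wc = spatial
        r0 = center[0] - wr // 2
        c0 = center[1] - wc // 2
        win = np.zeros((wr, wc))
        for i in range(wr):
            for j in range(wc):
                r, c = r0 + i, c0 + j
                if 0 <= r < rows and 0 <= c < cols:
                    win[i, j] = self.spatial[r, c]
        v = np.einsum("t,rc->trc", self.temporal, win).ravel()
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("window does not overlap the filter support")
        return v / n


@dataclass(frozen=True)
class NonlinearitySpec:
    """Static nonlinearity g mapping filter output to expected spikes/frame.

    rate(x) = gain * g(x) + baseline, with g one of
    ``rectified_on`` [x]+^p, ``rectified_off`` [-x]+^p, ``symmetric`` |x|^p,
    or ``unbalanced`` w_on*[x]+^p + w_off*[-x]+^p.
    """

    kind: str
    gain: float = 1.0
    baseline: float = 0.005
    exponent: float = 1.0
    w_on: float = 1.0
    w_off: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rectified_on", "rectified_off", "symmetric", "unbalanced"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.gain < 0 or self.baseline < 0:
            raise ValueError("gain and baseline must be non-negative")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")

    def g(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.exponent
        pos = np.maximum(x, 0.0) ** p
        neg = np.maximum(-x, 0.0) ** p
        if self.kind == "rectified_on":
            return pos
        if self.kind == "rectified_off":
            return neg
        if self.kind == "symmetric":
            return pos + neg  # == |x|**p
        return self.w_on * pos + self.w_off * neg

    def rate(self, x: np.ndarray) -> np.ndarray:
        """Expected spike count per frame given filter output x."""
        return self.gain * self.g(x) + self.baseline


@dataclass
class SyntheticCell:
    id: str
    filter: GroundTruthFilter
    nonlinearity: NonlinearitySpec
    true_label: str
    # optional second filter with its own temporal kernel driving the OFF
    # lobe, emulating temporally mismatched ON/OFF pathways (slow-OFF cells)
    off_filter: Optional[GroundTruthFilter] = None

    def __post_init__(self) -> None:
        if self.true_label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


def _halfmoment(sigma: float, p: float) -> float:
    """E[max(X,0)^p] for X ~ N(0, sigma^2)."""
    return 0.5 * sigma**p * 2.0 ** (p / 2.0) * gamma_fn((p + 1) / 2.0) / np.sqrt(np.pi)


def calibrate_gain(
    spec_kind: str,
    target_rate: float,
    baseline: float,
    proj_sd: float,
    exponent: float = 1.0,
    w_on: float = 1.0,
    w_off: float = 1.0,
) -> float:
    """Gain giving an expected ``target_rate`` spikes/frame under a Gaussian
    filter-output distribution of s.d. ``proj_sd``."""
    h = _halfmoment(proj_sd, exponent)
    if spec_kind in ("rectified_on", "rectified_off"):
        eg = h
    elif spec_kind == "symmetric":
        eg = 2.0 * h
    elif spec_kind == "unbalanced":
        eg = (w_on + w_off) * h
    else:
        raise ValueError(spec_kind)
    if target_rate <= baseline:
        raise ValueError("target_rate must exceed baseline")
    return (target_rate - baseline) / eg


def _spatial_gaussian(
    config: StimulusConfig,
    center_um: tuple[float, float],
    sigma_um: tuple[float, float],
    theta: float,
) -> np.ndarray:
    cs = config.checker_size_um
    x = (np.arange(config.grid_cols) + 0.5) * cs
    y = (np.arange(config.grid_rows) + 0.5) * cs
    xx, yy = np.meshgrid(x, y)
    h, k = center_um
    sa, sb = sigma_um
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - h) * ct + (yy - k) * st
    v = -(xx - h) * st + (yy - k) * ct
    return np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))


def make_cell(
    label: str,
    config: StimulusConfig,
    center_um: tuple[float, float],
    spatial_sigma_um: float | tuple[float, float] = 70.0,
    theta: float = 0.0,
    f: int = 20,
    temporal_params: dict | None = None,
    nonlinearity: NonlinearitySpec | None = None,
    target_rate: float = 0.14,
    cell_id: str = "cell",
) -> SyntheticCell:
    """Construct a ground-truth cell of the given label.

    If no nonlinearity is supplied, the label picks one (ON -> rectified_on,
    OFF -> rectified_off, ON_OFF -> symmetric |x|) and the gain is
    calibrated analytically so the cell fires ~``target_rate`` spikes per
    frame under the configured white noise.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    w = config.grid_cols * config.checker_size_um
    hgt = config.grid_rows * config.checker_size_um
    if not (0 <= center_um[0] <= w and 0 <= center_um[1] <= hgt):
        raise ValueError("center outside grid")
    if np.isscalar(spatial_sigma_um):
        spatial_sigma_um = (float(spatial_sigma_um), float(spatial_sigma_um))
    if min(spatial_sigma_um) <= 0:
        raise ValueError("spatial_sigma must be positive")
    spatial = _spatial_gaussian(config, center_um, spatial_sigma_um, theta)
    temporal = biphasic_kernel(f, **(temporal_params or {}))
    filt = GroundTruthFilter(
        spatial=spatial,
        temporal=temporal,
        config=config,
        center_um=center_um,
        sigma_um=spatial_sigma_um,
        theta=theta,
    )
    if nonlinearity is None:
        # default cells are expansive (power-2) rectifiers: half-squaring
        # ON/OFF pathways and a squared (energy-detector) ON-OFF cell, the
        # standard LNP description of these classes
        kind = {"ON": "rectified_on", "OFF": "rectified_off", "ON_OFF": "symmetric"}[label]
        baseline = 0.005
        exponent = 2.0
        gain = calibrate_gain(
            kind, target_rate, baseline, truncated_gaussian_sd(config), exponent=exponent
        )
        nonlinearity = NonlinearitySpec(
            kind=kind, gain=gain, baseline=baseline, exponent=exponent
        )
    return SyntheticCell(
        id=cell_id, filter=filt, nonlinearity=nonlinearity, true_label=label
    )


def _filter_projection(filt: GroundTruthFilter, movie: FrameSequence) -> np.ndarray:
    """Projection of the unit-norm filter onto each frame's f-frame history.

    Returns an array over frames t = f .. T-1 (aligned so element i is the
    projection for spike bin t = f + i); uses the space-time separability
    of the ground-truth filter for speed.
    """
    f = filt.f
    T = movie.n_frames
    if T <= f:
        raise ValueError("movie shorter than the filter history")
    sp = movie.frames.reshape(T, -1) @ filt.spatial.ravel()
    norm = np.linalg.norm(filt.temporal) * np.linalg.norm(filt.spatial)
    conv = np.convolve(sp, filt.temporal[::-1])
    return conv[f - 1 : T - 1] / norm


def simulate_spikes(
    cell: SyntheticCell,
    movie: FrameSequence,
    seed: int = 0,
) -> SpikeTrain:
    """Draw a Poisson spike train from the cell's LN cascade.

    For each frame t >= f the spike count is Poisson with mean
    ``rate(k . s_t)`` where s_t is the linearized f-frame stimulus history;
    spike times are placed uniformly within the frame bin (downstream
    binning re-quantizes them, so placement is immaterial).
    """
    f = cell.filter.f
    proj = _filter_projection(cell.filter, movie)
    nl = cell.nonlinearity
    if cell.off_filter is not None:
        proj_off = _filter_projection(cell.off_filter, movie)
        p = nl.exponent
        rates = nl.gain * (
            nl.w_on * np.maximum(proj, 0.0) ** p
            + nl.w_off * np.maximum(-proj_off, 0.0) ** p
        ) + nl.baseline
    else:
        rates = nl.rate(proj)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates)
    dt = movie.config.frame_interval_s
    times = []
    spike_bins = np.nonzero(counts)[0]
    for i in spike_bins:
        t0 = movie.frame_times[f + i]
        times.append(t0 + rng.random(counts[i]) * dt)
    all_times = np.sort(np.concatenate(times)) if times else np.empty(0)
    return SpikeTrain(unit_id=cell.id, times=all_times)


def make_population(
    n_on: int,
    n_off: int,
    n_onoff: int,
    config: StimulusConfig,
    seed: int = 0,
    f: int = 20,
    sigma_range_um: tuple[float, float] = (60.0, 100.0),
    edge_margin_checkers: float = 2.5,
    target_rate: float = 0.14,
) -> list[SyntheticCell]:
    """A population of cells with randomized centers and sizes.

    Centers are uniform over the grid interior (keeping ``edge_margin_checkers``
    clear of each edge so 5x5 windows need no padding); spatial sigmas are
    uniform over ``sigma_range_um``.
    """
    if n_on < 0 or n_off < 0 or n_onoff < 0:
        raise ValueError("counts must be non-negative")
    if n_on + n_off + n_onoff == 0:
        raise ValueError("population must contain at least one cell")
    rng = np.random.default_rng(seed)
    cs = config.checker_size_um
    m = edge_margin_checkers * cs
    cells: list[SyntheticCell] = []
    labels = ["ON"] * n_on + ["OFF"] * n_off + ["ON_OFF"] * n_onoff
    for i, label in enumerate(labels):
        h = rng.uniform(m, config.grid_cols * cs - m)
        k = rng.uniform(m, config.grid_rows * cs - m)
        sig = rng.uniform(*sigma_range_um)
        cells.append(
            make_cell(
                label,
                config,
                center_um=(h, k),
                spatial_sigma_um=sig,
                f=f,
                target_rate=target_rate,
                cell_id=f"{label.lower()}_{i:03d}",
            )
        )
    return cells


def population_truth_table(cells: list[SyntheticCell]):
    """Ground-truth table (id, label, center, sigma, gain) as a DataFrame."""
    import pandas as pd

    rows = []
    for c in cells:
        rows.append(
            {
                "unit_id": c.id,
                "true_label": c.true_label,
                "center_x_um": c.filter.center_um[0],
                "center_y_um": c.filter.center_um[1],
                "sigma_a_um": c.filter.sigma_um[0],
                "sigma_b_um": c.filter.sigma_um[1],
                "gain": c.nonlinearity.gain,
                "baseline": c.nonlinearity.baseline,
                "kind": c.nonlinearity.kind,
            }
        )
    return pd.DataFrame(rows)
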