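"""Spike binning and construction of the spike-triggered ensemble (STE).

The STE is the N x M matrix whose rows are the linearized spatiotemporal
stimulus vectors preceding each spike; the raw stimulus set (RSS) holds the
same vectors for *every* frame position.  Row layout is frame-major with
the oldest frame first, then row-major in space; the layout is recorded on
the ensemble so filters round-trip through export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .stimulus import FrameSequence

__all__ = [
    "SpikeTrain",
    "BinnedSpikes",
    "SpikeTriggeredEnsemble",
    "bin_spikes",
    "build_ste",
    "build_rss",
    "window_ste",
    "find_center_checker",
]

LAYOUT = "frame_major_then_row_major"


@dataclass
class SpikeTrain:
    """Spike times (seconds) of one unit, sorted ascending."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted ascending")
        if self.times.size and self.times[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class BinnedSpikes:
    """Per-frame spike counts on the stimulus clock, plus the number of
    spikes that fell outside the covered interval."""

    counts: np.ndarray
    n_dropped: int

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())


@dataclass
class SpikeTriggeredEnsemble:
    """N x M matrix of stimulus vectors preceding spikes.

    ``window`` is the (rows, cols) spatial extent of each vector and
    ``origin`` the grid index of its top-left checker (negative when the
    window was zero-padded past the grid edge); ``pad_mask`` marks padded
    spatial positions.  M = f * rows * cols.
    """

    S: np.ndarray
    f: int
    window: tuple[int, int]
    origin: tuple[int, int] = (0, 0)
    pad_mask: Optional[np.ndarray] = None
    n_dropped: int = 0
    layout: str = LAYOUT

    def __post_init__(self) -> None:
        if self.S.ndim != 2:
            raise ValueError("S must be 2-D")
        if self.S.shape[1] != self.f * self.window[0] * self.window[1]:
            raise ValueError("M must equal f * window_rows * window_cols")

    @property
    def n_spikes(self) -> int:
        return self.S.shape[0]

    @property
    def M(self) -> int:
        return self.S.shape[1]

    @property
    def shape3(self) -> tuple[int, int, int]:
        return (self.f, self.window[0], self.window[1])

    def save(self, path: str | Path) -> None:
        import json

        path = Path(path)
        self.S.astype(np.float32).tofile(path)
        sidecar = {
            "N": int(self.n_spikes),
            "M": int(self.M),
            "f": self.f,
            "window": list(self.window),
            "origin": list(self.origin),
            "layout": self.layout,
            "n_dropped": self.n_dropped,
            "dtype": "float32",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def bin_spikes(train: SpikeTrain, frame_times: np.ndarray) -> BinnedSpikes:
    """Place spikes into frame bins [t_i, t_{i+1}) on the stimulus clock.

    The last bin extends one frame interval past the final onset.  A spike
    exactly on a bin boundary goes to the later bin (half-open convention).
    Spikes before the first frame or after the last bin are dropped and
    counted in ``n_dropped``.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size and np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    T = frame_times.size
    dt = frame_times[-1] - frame_times[-2] if T > 1 else 0.0
    idx = np.searchsorted(frame_times, train.times, side="right") - 1
    in_range = (idx >= 0) & (
        (idx < T - 1) | (train.times < frame_times[-1] + dt)
    )
    counts = np.bincount(idx[in_range], minlength=T)
    return BinnedSpikes(counts=counts, n_dropped=int((~in_range).sum()))


def _crop_frames(
    frames: np.ndarray, center: tuple[int, int], spatial: tuple[int, int]
) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """Spatially crop (T, rows, cols) around ``center``, zero-padding past
    the grid edge.  Returns (cropped, origin, pad_mask)."""
    T, rows, cols = frames.shape
    wr, wc = spatial
    r0 = center[0] - wr // 2
    c0 = center[1] - wc // 2
    if not (0 <= center[0] < rows and 0 <= center[1] < cols):
        raise ValueError("window center outside the grid")
    out = np.zeros((T, wr, wc), dtype=frames.dtype)
    pad = np.ones((wr, wc), dtype=bool)
    rlo, rhi = max(r0, 0), min(r0 + wr, rows)
    clo, chi = max(c0, 0), min(c0 + wc, cols)
    out[:, rlo - r0 : rhi - r0, clo - c0 : chi - c0] = frames[:, rlo:rhi, clo:chi]
    pad[rlo - r0 : rhi - r0, clo - c0 : chi - c0] = False
    return out, (r0, c0), pad


def _gather_rows(frames: np.ndarray, bins: np.ndarray, f: int) -> np.ndarray:
    """Rows of stimulus history (frames t-f .. t-1, linearized) for each
    spike bin t in ``bins`` (all >= f)."""
    sw = sliding_window_view(frames, f, axis=0)  # (T-f+1, rows, cols, f)
    picked = sw[bins - f]  # (N, rows, cols, f)
    return np.ascontiguousarray(picked.transpose(0, 3, 1, 2)).reshape(len(bins), -1)


def build_ste(
    movie: FrameSequence,
    counts: np.ndarray | BinnedSpikes,
    f: int,
    center: tuple[int, int] | None = None,
    spatial: tuple[int, int] | None = None,
) -> SpikeTriggeredEnsemble:
    """Build the STE from per-frame spike counts.

    A bin with count c contributes c identical rows, so N equals the total
    number of eligible spikes.  Spikes in the first f bins (not enough
    stimulus history) are dropped and counted.  With ``center``/``spatial``
    given, vectors are windowed spatially during construction.
    """
    if isinstance(counts, BinnedSpikes):
        counts = counts.counts
    counts = np.asarray(counts)
    if f < 1:
        raise ValueError("f must be >= 1")
    if movie.n_frames < f:
        raise ValueError("movie shorter than the requested history")
    frames = movie.frames
    origin, pad = (0, 0), None
    if spatial is not None:
        if center is None:
            raise ValueError("spatial windowing requires a center checker")
        frames, origin, pad = _crop_frames(frames, center, spatial)
    T = frames.shape[0]
    occupied = np.nonzero(counts[: T])[0]
    bins = np.repeat(occupied, counts[occupied])
    eligible = bins >= f
    n_dropped = int((~eligible).sum())
    bins = bins[eligible]
    S = _gather_rows(frames, bins, f)
    return SpikeTriggeredEnsemble(
        S=S,
        f=f,
        window=(frames.shape[1], frames.shape[2]),
        origin=origin,
        pad_mask=pad,
        n_dropped=n_dropped,
    )


def build_rss(
    movie: FrameSequence,
    f: int,
    center: tuple[int, int] | None = None,
    spatial: tuple[int, int] | None = None,
    max_samples: int | None = None,
    seed: int = 0,
) -> SpikeTriggeredEnsemble:
    """The raw stimulus set: one row per frame position t >= f, with the
    same windowing semantics as :func:`build_ste`.  ``max_samples`` draws a
    random subsample without replacement for long recordings."""
    if movie.n_frames <= f:
        raise ValueError("movie shorter than the requested history")
    frames = movie.frames
    origin, pad = (0, 0), None
    if spatial is not None:
        if center is None:
            raise ValueError("spatial windowing requires a center checker")
        frames, origin, pad = _crop_frames(frames, center, spatial)
    bins = np.arange(f, frames.shape[0])
    if max_samples is not None and max_samples < bins.size:
        rng = np.random.default_rng(seed)
        bins = np.sort(rng.choice(bins, size=max_samples, replace=False))
    S = _gather_rows(frames, bins, f)
    return SpikeTriggeredEnsemble(
        S=S, f=f, window=(frames.shape[1], frames.shape[2]), origin=origin, pad_mask=pad
    )


def window_ste(
    ste: SpikeTriggeredEnsemble,
    center: tuple[int, int],
    spatial: tuple[int, int] = (5, 5),
    f: int | None = None,
) -> SpikeTriggeredEnsemble:
    """Restrict an existing ensemble to a spatial window and/or a shorter
    (most recent) history.

    ``center`` is in the coordinate frame of the *source grid* (the same
    frame returned by :func:`find_center_checker`); windows reaching past
    the stored extent are zero-padded and flagged in ``pad_mask``.
    """
    f_new = ste.f if f is None else f
    if f_new > ste.f:
        raise ValueError("cannot extend history beyond the stored f")
    X = ste.S.reshape(ste.n_spikes, *ste.shape3)[:, ste.f - f_new :]
    # shift center into the stored window's local coordinates
    local = (center[0] - ste.origin[0], center[1] - ste.origin[1])
    N = ste.n_spikes
    flat = X.reshape(N * f_new, ste.window[0], ste.window[1])
    cropped, local_origin, pad = _crop_frames(flat, local, spatial)
    S = cropped.reshape(N, -1)
    origin = (ste.origin[0] + local_origin[0], ste.origin[1] + local_origin[1])
    if ste.pad_mask is not None:
        # positions padded in the source stay padded here
        src = np.zeros(ste.window, dtype=bool)
        src[:] = ste.pad_mask
        grown, _, _ = _crop_frames(
            (~src[None]).astype(float), local, spatial
        )
        pad = pad | (grown[0] == 0)
    return SpikeTriggeredEnsemble(
        S=S,
        f=f_new,
        window=spatial,
        origin=origin,
        pad_mask=pad,
        n_dropped=ste.n_dropped,
    )


def find_center_checker(sta) -> tuple[int, int]:
    """Grid (row, col) of the filter element with maximal absolute
    contrast; ties break toward the earliest (frame, row, col) in layout
    order.  Accepts a LinearFilter or a (f, rows, cols) array."""
    if hasattr(sta, "vector"):
        arr = np.asarray(sta.vector).reshape(sta.shape3)
        origin = getattr(sta, "origin", (0, 0))
    else:
        arr = np.asarray(sta)
        origin = (0, 0)
    if arr.ndim != 3:
        raise ValueError("expected a (f, rows, cols) filter")
    if not np.any(arr):
        raise ValueError("all-zero filter has no center")
    fi, r, c = np.unravel_index(np.argmax(np.abs(arr)), arr.shape)
    return (int(r) + origin[0], int(c) + origin[1])
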