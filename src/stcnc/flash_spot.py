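"""PSTHs, the full-field Response Dominance Index, and the Spot Bias.

Both indices are normalized differences of peak firing rates to light
increments versus decrements, (R_ON - R_OFF) / (R_ON + R_OFF) in [-1, 1]:
computed from the full-field flash phases for the RDI and from
single-checker spot flashes at the RF center for the spot bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import SpikeTrain
from .stimulus import FlashProtocol, SpotProtocol

__all__ = [
    "PSTH",
    "DominanceIndex",
    "compute_psth",
    "compute_rdi",
    "compute_spot_bias",
    "flash_rdi",
    "spot_bias_for_checker",
]


@dataclass
class PSTH:
    """Trial-averaged firing rate (spikes/s) in uniform bins relative to
    event onset."""

    bin_edges: np.ndarray
    rates: np.ndarray
    n_events: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peak_rate(self, t_start: float = 0.0, t_stop: float | None = None) -> float:
        sel = self.bin_centers >= t_start
        if t_stop is not None:
            sel &= self.bin_centers < t_stop
        if not sel.any():
            raise ValueError("no PSTH bins in the requested window")
        return float(self.rates[sel].max())


@dataclass
class DominanceIndex:
    value: float
    r_on: float
    r_off: float
    kind: str  # full_field_RDI | spot_bias


def compute_psth(
    train: SpikeTrain,
    event_times: np.ndarray,
    window_s: float,
    bin_width_s: float = 0.010,
) -> PSTH:
    """rate[b] = spikes in bin b pooled over events / (n_events * bin_width)."""
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        raise ValueError("need at least one event")
    n_bins = int(round(window_s / bin_width_s))
    edges = np.arange(n_bins + 1) * bin_width_s
    counts = np.zeros(n_bins)
    for t0 in event_times:
        rel = train.times - t0
        rel = rel[(rel >= 0) & (rel < n_bins * bin_width_s)]
        counts += np.histogram(rel, bins=edges)[0]
    rates = counts / (event_times.size * bin_width_s)
    return PSTH(bin_edges=edges, rates=rates, n_events=event_times.size)


def _index(r_on: float, r_off: float, kind: str) -> DominanceIndex:
    if r_on + r_off == 0:
        raise ValueError("both peak rates are zero: index undefined")
    return DominanceIndex(
        value=float((r_on - r_off) / (r_on + r_off)), r_on=r_on, r_off=r_off, kind=kind
    )


def compute_rdi(psth_on: PSTH, psth_off: PSTH, peak_window_s: float = 0.5) -> DominanceIndex:
    """Response Dominance Index from the transient peaks in the first
    quarter (0.5 s of a 2 s phase) of the ON and OFF phases."""
    r_on = psth_on.peak_rate(0.0, peak_window_s)
    r_off = psth_off.peak_rate(0.0, peak_window_s)
    return _index(r_on, r_off, "full_field_RDI")


def compute_spot_bias(
    psth_bright: PSTH, psth_dark: PSTH, peak_window_s: float = 0.5
) -> DominanceIndex:
    """Spot bias from the peak rates in the first 500 ms after bright-spot
    and dark-spot onsets at the RF-center checker."""
    r_on = psth_bright.peak_rate(0.0, peak_window_s)
    r_off = psth_dark.peak_rate(0.0, peak_window_s)
    return _index(r_on, r_off, "spot_bias")


def flash_rdi(
    train: SpikeTrain, protocol: FlashProtocol, bin_width_s: float = 0.010
) -> DominanceIndex:
    """RDI of one unit over a full-field flash protocol."""
    psth_on = compute_psth(train, protocol.on_onsets, protocol.on_duration_s, bin_width_s)
    psth_off = compute_psth(train, protocol.off_onsets, protocol.off_duration_s, bin_width_s)
    return compute_rdi(psth_on, psth_off, peak_window_s=protocol.on_duration_s / 4.0)


def spot_bias_for_checker(
    train: SpikeTrain,
    protocol: SpotProtocol,
    checker: tuple[int, int],
    bin_width_s: float = 0.010,
    window_s: float = 0.5,
) -> DominanceIndex:
    """Spot bias for the events that flashed the given checker."""
    ev = protocol.events
    at = (ev["row"] == checker[0]) & (ev["col"] == checker[1])
    bright = ev["time_s"][at & (ev["polarity"] > 0)]
    dark = ev["time_s"][at & (ev["polarity"] < 0)]
    if bright.size == 0 or dark.size == 0:
        raise ValueError("no spot events at the requested checker")
    return compute_spot_bias(
        compute_psth(train, bright, window_s, bin_width_s),
        compute_psth(train, dark, window_s, bin_width_s),
    )
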