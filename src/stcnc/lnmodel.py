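"""Static-nonlinearity recovery and ON/OFF bias from 1-D projections.

Projecting the raw stimulus set (RSS) and the spike-triggered ensemble
(STE) onto an oriented linear filter gives two histograms; their
element-wise ratio N = L_STE / L_RSS is the expected fractional spike
count per frame as a function of filter output.  Integrating N over the
positive and negative filter-output ranges yields P_ON and P_OFF and the
bias (P_ON - P_OFF) / (P_ON + P_OFF) in [-1, 1]: near +1 for ON cells,
near -1 for OFF cells, near 0 for ON-OFF cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ensemble import SpikeTriggeredEnsemble
from .moments import LinearFilter, compute_sta

__all__ = [
    "ProjectionHistogram",
    "StaticNonlinearity",
    "SplitFilters",
    "orient_filter",
    "project_and_bin",
    "pooled_rss_histogram",
    "recover_nonlinearity",
    "compute_bias",
    "split_spikes",
]


@dataclass
class ProjectionHistogram:
    """Binned filter outputs for the RSS and the STE on a common grid.

    Bins are uniform and span +/- ``span_sd`` (2.5 by default) standard
    deviations of the RSS projection; projections beyond the span are
    discarded (the stimulus distribution itself is truncated there) and
    their counts recorded.
    """

    bin_edges: np.ndarray
    L_RSS: np.ndarray
    L_STE: np.ndarray
    rss_sd: float
    discarded_rss: int = 0
    discarded_ste: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class StaticNonlinearity:
    """Expected spikes per frame per projection bin, with its ON/OFF
    integrals and bias."""

    bin_centers: np.ndarray
    N: np.ndarray
    p_on: float
    p_off: float

    @property
    def bias(self) -> float:
        denom = self.p_on + self.p_off
        if denom == 0:
            raise ValueError("bias undefined: P_ON + P_OFF = 0")
        return float((self.p_on - self.p_off) / denom)


@dataclass
class SplitFilters:
    """STAs computed separately from positive-projection (ON-type) and
    negative-projection (OFF-type) spikes."""

    sta_on: Optional[LinearFilter]
    sta_off: Optional[LinearFilter]
    n_on: int
    n_off: int


def orient_filter(filt: LinearFilter) -> tuple[LinearFilter, bool]:
    """Flip an OFF-type filter so it appears ON-type.

    The filter is negated iff its element of maximal absolute value is
    negative; returns (oriented filter, flipped?).  Idempotent.
    """
    v = filt.vector
    if not np.any(v):
        raise ValueError("cannot orient a zero filter")
    flip = v[int(np.argmax(np.abs(v)))] < 0
    if not flip:
        return filt, False
    return (
        LinearFilter(
            vector=-v,
            shape3=filt.shape3,
            kind=filt.kind,
            eigenvalue=filt.eigenvalue,
            signal_strength=filt.signal_strength,
            origin=filt.origin,
            pad_mask=filt.pad_mask,
        ),
        True,
    )


def project_and_bin(
    filt: LinearFilter,
    rss: SpikeTriggeredEnsemble,
    ste: SpikeTriggeredEnsemble,
    n_bins: int = 25,
    span_sd: float = 2.5,
    shared_rss: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> ProjectionHistogram:
    """Dot the (oriented) filter with every RSS and STE vector and bin the
    outputs on a uniform grid spanning +/- span_sd RSS standard deviations.

    The filter is normalized to unit length first, so the recovered
    nonlinearity depends only on the projection *direction*.  Passing the
    output of :func:`pooled_rss_histogram` as ``shared_rss`` skips the
    per-filter RSS projection (a speed option for large populations).
    """
    if rss is not None and rss.n_spikes == 0:
        raise ValueError("empty RSS sample")
    v = filt.vector / np.linalg.norm(filt.vector)
    if ste.M != v.size:
        raise ValueError("filter and ensembles live in different spaces")
    p_ste = ste.S @ v
    if shared_rss is not None:
        edges, l_rss, sd = shared_rss
        n_rss = int(round(l_rss.sum()))
    else:
        if rss.M != v.size:
            raise ValueError("filter and ensembles live in different spaces")
        p_rss = rss.S @ v
        sd = float(p_rss.std())
        edges = np.linspace(-span_sd * sd, span_sd * sd, n_bins + 1)
        l_rss, _ = np.histogram(p_rss, bins=edges)
        n_rss = p_rss.size
    l_ste, _ = np.histogram(p_ste, bins=edges)
    return ProjectionHistogram(
        bin_edges=edges,
        L_RSS=l_rss,
        L_STE=l_ste,
        rss_sd=sd,
        discarded_rss=int(n_rss - l_rss.sum()),
        discarded_ste=int(p_ste.size - l_ste.sum()),
    )


def pooled_rss_histogram(
    rss: SpikeTriggeredEnsemble,
    n_filters: int = 10,
    n_bins: int = 25,
    span_sd: float = 2.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """An L_RSS shared across units, averaged over random unit filters.

    Because the white-noise RSS is nearly isotropic, its projection
    histogram barely depends on the filter direction; pooling the
    projections of ``n_filters`` random unit vectors gives one reusable
    L_RSS (scaled back to a single filter's sample size).  Returns
    (bin_edges, L_RSS, rss_sd).
    """
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((rss.M, n_filters))
    V /= np.linalg.norm(V, axis=0)
    proj = (rss.S @ V).ravel()
    sd = float(proj.std())
    edges = np.linspace(-span_sd * sd, span_sd * sd, n_bins + 1)
    counts, _ = np.histogram(proj, bins=edges)
    return edges, counts / n_filters, sd


def recover_nonlinearity(hist: ProjectionHistogram) -> StaticNonlinearity:
    """N = L_STE / L_RSS element-wise; empty RSS bins are dropped.

    Values can exceed 1 when more than one spike is expected per frame.
    P_ON and P_OFF are trapezoidal integrals of N over the positive and
    negative bin-center ranges.
    """
    occ = hist.L_RSS > 0
    if not occ.any():
        raise ValueError("all RSS bins empty")
    x = hist.bin_centers[occ]
    N = hist.L_STE[occ] / hist.L_RSS[occ]
    p_on = _halfline_integral(x, N, positive=True)
    p_off = _halfline_integral(x, N, positive=False)
    return StaticNonlinearity(bin_centers=x, N=N, p_on=p_on, p_off=p_off)


def _halfline_integral(x: np.ndarray, y: np.ndarray, positive: bool) -> float:
    sel = x > 0 if positive else x < 0
    if sel.sum() < 2:
        return float(y[sel].sum()) * (abs(float(np.diff(x).mean())) if x.size > 1 else 1.0)
    return float(abs(np.trapezoid(y[sel], x[sel])))


def compute_bias(nl: StaticNonlinearity) -> float:
    """(P_ON - P_OFF) / (P_ON + P_OFF), in [-1, 1]."""
    return nl.bias


def split_spikes(
    filt: LinearFilter, ste: SpikeTriggeredEnsemble
) -> SplitFilters:
    """Separate ON-type from OFF-type spikes by the sign of the projection
    onto the oriented filter, and compute an STA within each set.

    Zero projections count as ON; an empty side yields a missing filter.
    """
    v = filt.vector / np.linalg.norm(filt.vector)
    proj = ste.S @ v
    on = proj >= 0
    parts = {}
    for name, mask in (("on", on), ("off", ~on)):
        if mask.sum() == 0:
            parts[name] = None
            continue
        sub = SpikeTriggeredEnsemble(
            S=ste.S[mask],
            f=ste.f,
            window=ste.window,
            origin=ste.origin,
            pad_mask=ste.pad_mask,
        )
        sta = compute_sta(sub)
        sta.kind = f"STA_{name.upper()}"
        parts[name] = sta
    return SplitFilters(
        sta_on=parts["on"],
        sta_off=parts["off"],
        n_on=int(on.sum()),
        n_off=int((~on).sum()),
    )
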