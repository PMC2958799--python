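"""First and second moments of the spike-triggered ensemble.

The spike-triggered average (STA) is the ensemble mean; the centered
covariance C and the non-centered second-moment matrix M = (1/N) S^T S are
eigendecomposed to find directions of, respectively, maximal STE variance
and maximal second moment *about zero contrast*.  For a cell with an
even-symmetric nonlinearity the STA cancels while the top eigenvector of M
still recovers the linear filter — that asymmetry is the point of the
non-centered analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ensemble import SpikeTriggeredEnsemble, _crop_frames
from .stimulus import FrameSequence

__all__ = [
    "LinearFilter",
    "MomentMatrices",
    "ConvergenceCurve",
    "compute_sta",
    "compute_sta_streaming",
    "compute_energy_map",
    "find_center_from_energy",
    "compute_covariance",
    "compute_noncentered_moment",
    "compute_moments",
    "stc_nc_filter",
    "stc_spectrum",
    "project_out_sta",
    "sta_signal_strength",
    "stcnc_signal_strength",
    "convergence_curve",
]


@dataclass
class LinearFilter:
    """A linearized spatiotemporal filter (STA, STC eigenvector, or the
    STC-NC vector) with its spatial/temporal shape metadata.

    ``vector`` follows the ensemble layout (frame-major, oldest frame
    first, then row-major space); ``origin`` locates the spatial window on
    the source grid and ``pad_mask`` marks zero-padded positions.
    """

    vector: np.ndarray
    shape3: tuple[int, int, int]
    kind: str = "STA"
    eigenvalue: Optional[float] = None
    signal_strength: Optional[float] = None
    origin: tuple[int, int] = (0, 0)
    pad_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if self.vector.size != int(np.prod(self.shape3)):
            raise ValueError("vector length must equal f * rows * cols")

    @property
    def f(self) -> int:
        return self.shape3[0]

    @property
    def as_3d(self) -> np.ndarray:
        return self.vector.reshape(self.shape3)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))

    def save(self, path) -> None:
        """Binary float32 vector plus a JSON sidecar with shape/layout."""
        import json
        from pathlib import Path

        path = Path(path)
        self.vector.astype(np.float32).tofile(path)
        sidecar = {
            "shape": list(self.shape3),
            "kind": self.kind,
            "eigenvalue": self.eigenvalue,
            "signal_strength": self.signal_strength,
            "origin": list(self.origin),
            "layout": "frame_major_then_row_major",
            "dtype": "float32",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    def window(
        self, center: tuple[int, int], spatial: tuple[int, int], f: int | None = None
    ) -> "LinearFilter":
        """Restrict the filter to a spatial window / shorter history, with
        the same conventions as ensemble windowing."""
        f_new = self.f if f is None else f
        arr = self.as_3d[self.f - f_new :]
        local = (center[0] - self.origin[0], center[1] - self.origin[1])
        cropped, local_origin, pad = _crop_frames(arr, local, spatial)
        return LinearFilter(
            vector=cropped.ravel(),
            shape3=(f_new, spatial[0], spatial[1]),
            kind=self.kind,
            origin=(self.origin[0] + local_origin[0], self.origin[1] + local_origin[1]),
            pad_mask=pad,
        )


@dataclass
class MomentMatrices:
    """Centered covariance C (1/(N-1)) and non-centered second moment
    Mmat (1/N) of one ensemble."""

    C: np.ndarray
    Mmat: np.ndarray
    N_used: int


@dataclass
class ConvergenceCurve:
    """Projection of intermediate STC-NC estimates onto the final one,
    evaluated at fixed spike-count checkpoints."""

    checkpoints: np.ndarray
    projections: np.ndarray
    converged: bool


def compute_sta(ste: SpikeTriggeredEnsemble) -> LinearFilter:
    """The STA: the element-wise mean over rows of the ensemble."""
    if ste.n_spikes < 1:
        raise ValueError("empty ensemble")
    return LinearFilter(
        vector=ste.S.mean(axis=0),
        shape3=ste.shape3,
        kind="STA",
        origin=ste.origin,
        pad_mask=ste.pad_mask,
    )


def compute_sta_streaming(
    movie: FrameSequence, counts: np.ndarray, f: int
) -> LinearFilter:
    """STA on the full grid without materializing the ensemble.

    Averages the f-frame history over spike bins by direct correlation of
    the count vector with the movie; identical to the mean of the explicit
    ensemble rows, but O(T * c) memory instead of O(N * f * c).
    """
    counts = np.asarray(counts, dtype=float)
    T, rows, cols = movie.frames.shape
    if T < f + 1:
        raise ValueError("movie shorter than the requested history")
    w = counts[f:T]
    N = w.sum()
    if N < 1:
        raise ValueError("no eligible spikes")
    flat = movie.frames.reshape(T, -1)
    A = np.empty((f, rows * cols))
    for j in range(f):
        A[j] = w @ flat[j : T - f + j] / N
    return LinearFilter(vector=A.ravel(), shape3=(f, rows, cols), kind="STA")


def compute_energy_map(movie: FrameSequence, counts: np.ndarray, f: int) -> np.ndarray:
    """Spike-triggered second-moment map minus the raw-stimulus second
    moment, shape (f, rows, cols).

    This is the diagonal of the non-centered moment matrix on the full
    grid, referenced to the stimulus power, so it highlights checkers whose
    contrast *energy* — not its signed mean — predicts spiking.  It locates
    ON-OFF receptive fields whose STA cancels.
    """
    counts = np.asarray(counts, dtype=float)
    T = movie.n_frames
    w = counts[f:T]
    N = w.sum()
    if N < 1:
        raise ValueError("no eligible spikes")
    sq = movie.frames.reshape(T, -1) ** 2
    base = sq.mean(axis=0)
    E = np.empty((f, sq.shape[1]))
    for j in range(f):
        E[j] = w @ sq[j : T - f + j] / N - base
    return E.reshape(f, movie.frames.shape[1], movie.frames.shape[2])


def find_center_from_energy(
    movie: FrameSequence,
    counts: np.ndarray,
    f: int,
    spatial: tuple[int, int] = (5, 5),
    n_candidates: int = 8,
) -> tuple[int, int]:
    """RF-center checker from spike-triggered contrast energy.

    Per-checker energy deviations are summed over the f history frames and
    z-scored against their own spatial distribution; the strongest
    ``n_candidates`` checkers then compete as window centers, scored by the
    leading eigenvalue of the windowed non-centered second moment.  The
    two-stage search is what makes ON-OFF cells — whose STA carries no
    usable peak — localizable at realistic spike counts.
    """
    from .ensemble import build_ste

    E = compute_energy_map(movie, counts, f)
    per_checker = E.sum(axis=0)
    z = (per_checker - np.median(per_checker)) / (per_checker.std() + 1e-300)
    flat_order = np.argsort(np.abs(z).ravel())[::-1][:n_candidates]
    best, best_val = None, -np.inf
    for flat in flat_order:
        r, c = np.unravel_index(flat, z.shape)
        ste = build_ste(movie, counts, f, center=(int(r), int(c)), spatial=spatial)
        if ste.n_spikes == 0:
            continue
        Mmat = compute_noncentered_moment(ste)
        top = float(np.linalg.eigvalsh(Mmat)[-1])
        if top > best_val:
            best_val, best = top, (int(r), int(c))
    if best is None:
        raise ValueError("no eligible spikes for energy-based centering")
    return best


def compute_covariance(ste: SpikeTriggeredEnsemble) -> np.ndarray:
    """Centered covariance C = (1/(N-1)) sum (s_n - A)(s_n - A)^T."""
    N = ste.n_spikes
    if N < 2:
        raise ValueError("need at least two spikes for a covariance")
    Sc = ste.S - ste.S.mean(axis=0)
    C = Sc.T @ Sc / (N - 1)
    return (C + C.T) / 2.0


def compute_noncentered_moment(ste: SpikeTriggeredEnsemble) -> np.ndarray:
    """Non-centered second moment Mmat = (1/N) sum s_n s_n^T."""
    N = ste.n_spikes
    if N < 1:
        raise ValueError("empty ensemble")
    M = ste.S.T @ ste.S / N
    return (M + M.T) / 2.0


def compute_moments(ste: SpikeTriggeredEnsemble) -> MomentMatrices:
    return MomentMatrices(
        C=compute_covariance(ste),
        Mmat=compute_noncentered_moment(ste),
        N_used=ste.n_spikes,
    )


def _orient_sign(v: np.ndarray) -> np.ndarray:
    """Fix eigenvector sign so the element of maximal |value| is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def stc_nc_filter(
    Mmat: np.ndarray, ste: SpikeTriggeredEnsemble | None = None
) -> LinearFilter:
    """Leading eigenvector of the non-centered second-moment matrix.

    Unit norm, sign-oriented so the largest-|element| is positive.  Shape
    metadata is carried over from ``ste`` when provided.
    """
    Mmat = np.asarray(Mmat)
    if not np.allclose(Mmat, Mmat.T, atol=1e-8 * max(1.0, np.abs(Mmat).max())):
        raise ValueError("second-moment matrix must be symmetric")
    w, V = np.linalg.eigh(Mmat)
    v = _orient_sign(V[:, -1])
    meta = {}
    if ste is not None:
        meta = {"origin": ste.origin, "pad_mask": ste.pad_mask}
        shape3 = ste.shape3
    else:
        m = Mmat.shape[0]
        shape3 = (m, 1, 1)
    return LinearFilter(
        vector=v, shape3=shape3, kind="STC_NC", eigenvalue=float(w[-1]), **meta
    )


def stc_spectrum(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full eigendecomposition of the (centered) covariance, sorted by
    descending eigenvalue.  Returns (eigenvalues, eigenvectors-as-columns);
    the first column is the high-variance direction, the last the
    low-variance one."""
    C = np.asarray(C)
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance must be symmetric")
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    V = V[:, order]
    for j in range(V.shape[1]):
        V[:, j] = _orient_sign(V[:, j])
    return w[order], V


def project_out_sta(
    ste: SpikeTriggeredEnsemble, sta: LinearFilter
) -> SpikeTriggeredEnsemble:
    """Remove the STA direction from every ensemble row:
    s -> s - (s . a_hat) a_hat.  Idempotent; the result is orthogonal to
    the STA to round-off."""
    a = np.asarray(sta.vector, dtype=float)
    nrm = np.linalg.norm(a)
    if nrm == 0:
        raise ValueError("cannot project out a zero STA")
    a = a / nrm
    S = ste.S - np.outer(ste.S @ a, a)
    return SpikeTriggeredEnsemble(
        S=S,
        f=ste.f,
        window=ste.window,
        origin=ste.origin,
        pad_mask=ste.pad_mask,
        n_dropped=ste.n_dropped,
    )


def sta_signal_strength(sta: LinearFilter) -> float:
    """max |A_i| over the s.d. of all STA elements (signal included).

    A unit is considered non-responsive when no element reaches six of
    these standard deviations.
    """
    v = sta.vector
    sd = v.std()
    if sd == 0:
        raise ValueError("constant STA has undefined signal strength")
    return float(np.abs(v).max() / sd)


def stcnc_signal_strength(filt: LinearFilter) -> float:
    """max |element| over the s.d. of the outermost ring of window pixels
    (all frames pooled, zero-padded positions excluded).

    Because the window is small the receptive field fills much of it; the
    border ring estimates the noise floor instead of the full vector.
    """
    f, rows, cols = filt.shape3
    ring = np.zeros((rows, cols), dtype=bool)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    if filt.pad_mask is not None:
        ring &= ~filt.pad_mask
    if not ring.any():
        raise ValueError("all border positions are padded")
    arr = filt.as_3d
    sd = arr[:, ring].std()
    if sd == 0:
        raise ValueError("zero-variance border ring")
    return float(np.abs(arr).max() / sd)


def convergence_curve(
    ste: SpikeTriggeredEnsemble, step: int = 100, tol: float = 0.05
) -> ConvergenceCurve:
    """Recompute the STC-NC on the first k spikes at 100-spike intervals
    and project each intermediate unit vector onto the final one.

    The unit is labelled converged when, over the checkpoints in the second
    half of its spikes, the projection stays within ``tol`` (5%) of the
    final value of 1.
    """
    N = ste.n_spikes
    if N < 2 * step:
        raise ValueError("need at least two checkpoints worth of spikes")
    checkpoints = np.arange(step, N + 1, step)
    if checkpoints[-1] != N:
        checkpoints = np.append(checkpoints, N)
    # cumulative second-moment updates between checkpoints
    M = np.zeros((ste.M, ste.M))
    projections = np.empty(checkpoints.size)
    vecs = []
    prev = 0
    for i, k in enumerate(checkpoints):
        chunk = ste.S[prev:k]
        M += chunk.T @ chunk
        prev = k
        w, V = np.linalg.eigh((M + M.T) / (2.0 * k))
        vecs.append(V[:, -1])
    final = vecs[-1]
    for i, v in enumerate(vecs):
        projections[i] = abs(float(v @ final))
    second_half = checkpoints >= N / 2.0
    converged = bool(np.all(1.0 - projections[second_half] < tol))
    return ConvergenceCurve(
        checkpoints=checkpoints, projections=projections, converged=converged
    )
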