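# Methods

## The estimation problem

A spiking visual neuron under dense white noise is modelled as an LN
(linear–nonlinear) Poisson cascade: a linear spatiotemporal filter **k**
reduces the stimulus history to a scalar, a static nonlinearity g maps
that scalar to an expected spike count per frame, and spikes are Poisson.
The spike-triggered ensemble (STE) is the N×M matrix of stimulus vectors
preceding the N spikes; the raw stimulus set (RSS) holds the vectors for
all frame positions. All stimulus values are *contrasts* (deviation from
the mean luminance), so the RSS mean is the zero vector.

The STA (STE row mean) estimates **k** only when g is asymmetric about
zero. For an ON-OFF cell g is approximately even — bright and dark
stimuli along **k** both drive spikes — and the STA cancels toward zero
at any spike count. The STE's *second moment about zero*,
M = (1/N) Σ sₙsₙᵀ, is inflated along **k** regardless of g's symmetry:
spikes concentrate stimulus energy, not stimulus sign, on the filter.
Its leading eigenvector (the STC-NC filter) therefore recovers **k** for
ON, OFF and ON-OFF cells alike. The identity M = C_N + A·Aᵀ (C_N the
1/N-normalized covariance, A the STA) makes the relation to ordinary
spike-triggered covariance explicit and is verified numerically on every
test run. We use 1/(N−1) for the reported covariance C and 1/N for M;
eigenvectors are normalization-invariant, so only that identity depends
on the convention. Eigenvector signs are fixed by making the
largest-|element| positive; the underlying sign is arbitrary.

## Stimulus model and units

The checkerboard stimulus draws each checker's luminance independently
every frame from a Gaussian (mean 2 cd·m⁻², s.d. 0.78 cd·m⁻²) truncated
to the displayable range [0, 4] cd·m⁻² — i.e. at ±2.564 standard
deviations. Truncation is implemented by redrawing out-of-range values,
so the emitted distribution is exactly the truncated normal with no
probability atoms at the bounds (its s.d. is 0.749 cd·m⁻²). Frames renew
every 33 ms; checkers are 100 µm; grids default to 16×16. All of these
are configuration fields; a (config, seed, n_frames) triple regenerates a
movie bit-identically, so movies are never stored. Spatial indexing is
row-major and 0-based with checker (0,0) top-left; STE rows are laid out
frame-major (oldest frame first) then row-major in space, and that layout
is recorded on every ensemble and filter so they round-trip through
export.

Flash (2 s at 0 cd·m⁻², then 2 s at 4 cd·m⁻²) and spot protocols (one
randomly chosen checker per second at 0 or 4 cd·m⁻², ≥20 repeats per
location and polarity) are generated as event tables and can be rendered
onto the frame clock, so the same LN simulator that consumes white noise
also produces flash and spot responses.

## Synthetic cells

Ground-truth cells are space–time separable: an elliptical Gaussian
center (default σ 70 µm, population range 60–100 µm, matching RF-center
radii of tens of µm) times a biphasic temporal kernel over 20 frames
(difference of two gamma-like lobes, dominant lobe peaking ~3 frames =
100 ms before the spike), normalized to a unit M-vector. Nonlinearities
are rectifying for ON/OFF cells and even for ON-OFF cells, plus a small
spontaneous baseline (0.005 spikes/frame ≈ 0.15 Hz).

The default exponent is 2: ON/OFF cells half-square ([x]₊²) and ON-OFF
cells square (x²) their filter output. This is the standard expansive
output nonlinearity of LNP fits to ganglion cells, and it is what makes
the "near unity" agreement between STA and STC-NC filters of real
rectifying cells reproducible in simulation: with a linear rectifier the
spike-triggered second moment along the filter is only twice the bulk,
and at 5000 spikes in 500 dimensions the eigenvector overlap hovers near
0.85–0.90; with the expansive rectifier the ratio is 3 and overlaps sit
at 0.93–0.97. Piecewise-linear nonlinearities (including the |x| ON-OFF
variant and asymmetric w_on/w_off mixtures) remain available and are used
in the nonlinearity-recovery tests. Gains are calibrated analytically
from the half-moments of the Gaussian projection distribution so a cell
fires a target rate (default 0.14 spikes/frame ≈ 4.2 Hz, i.e. ~5000
spikes in a 36 000-frame ≈ 20-minute recording — the regime in which real
units' STC-NC estimates have converged).

Spike times are placed uniformly within their frame bin; downstream
binning re-quantizes to the frame clock, so placement is immaterial. A
"slow-OFF" variant (a second filter with a delayed kernel driving the
negative lobe) is supported but off by default; how strong that temporal
mismatch is in real ON-OFF cells is not well constrained.

What the simulator deliberately omits: spike-sorting artifacts,
refractoriness and adaptation, inter-cell correlations, and
center–surround antagonism. Passing tests therefore demonstrate
correctness of the estimators under the LN-Poisson model, not robustness
to every property of real recordings.

## Pipeline and gates

Per unit: spikes are binned half-open on the frame clock (boundary spikes
go to the later bin); the full-grid STA uses 30 frames of history; the
STC-NC uses a 5×5-checker window (M = 500 with 20 frames) centered on the
STA peak. A unit whose STA has no element reaching 6 s.d. of its own
elements is flagged STA-non-responsive; since a well-balanced ON-OFF cell
fails that test *by construction* while being strongly driven, the
window center then falls back to a spike-triggered energy map (the
diagonal of the full-grid second moment referenced to the stimulus
power, summed over frames and z-scored), whose top candidates compete by
the leading eigenvalue of their windowed second moment. Mappability for
classification uses the STC-NC ring strength: max |element| over the
s.d. of the window's outermost ring of checkers (padded positions
excluded), gated at 6. Pure-noise units score ~3–4 on this measure and
are excluded; driven units score 10–25.

The static nonlinearity is recovered on a 3×3 (300 µm) re-window: STE
and RSS projections onto the oriented unit filter are histogrammed in 25
uniform bins spanning ±2.5 RSS standard deviations (projections beyond
that are discarded, mirroring the stimulus truncation; ~1.2% of a
Gaussian), and N = L_STE/L_RSS. 25 bins keeps ≥50 expected RSS counts
per bin at 10⁴ RSS samples. OFF-type filters are negated first
("oriented") so the bias is comparable across classes; for a symmetric
cell the orientation is arbitrary and the bias is ≈0 either way. P_ON
and P_OFF are trapezoidal integrals of N over the positive/negative bin
ranges; rectangle sums differ by O(Δ²), far below the ±0.6 classification
resolution. Bias thresholds: OFF < −0.6, ON > +0.6, closed interval
between → ON-OFF. A pooled L_RSS averaged over 10 random unit filters is
available as a speed option for large populations; the RSS is close
enough to isotropic that it shifts biases by <0.05.

The dip statistic is computed on the same 1-D STE projections used for
the nonlinearity, with the classical greatest-convex-minorant /
least-concave-majorant algorithm (validated to 1e−13 against an
independent linear-programming search over discretized unimodal CDFs).
p-values bootstrap uniform samples of the same size (default 1000
replicates, seeded; the null distribution is cached per sample size
within a run). The dip is affine-invariant but *not* invariant under
nonlinear monotone transforms — unimodality of a density is not
preserved by reparameterization — which both implementations confirm.

## RF-center size

The single frame of maximal |contrast| is fit by least squares with
A·exp(−(a(x−h)² + 2b(x−h)(y−k) + c(y−k)²)), the rotated bivariate
Gaussian (major axis at angle θ to the x-axis; σₐ ≥ σᵦ enforced by
canonicalization, θ folded to [0, π)). The windowed frame is embedded in
5 rings of zero contrast ("large" border, loosely forcing the fit to
zero at the edges, as data points rather than constraints);
initialization comes from the thresholded-|z| centroid and second
moments; σ is bounded in [0.25 checkers, frame extent]; OFF frames fit
with A < 0. Optimizer failure sets a non-converged flag instead of
raising. RF area is the 1σ ellipse, π·σₐ·σᵦ.

The counting alternative takes checkers with |value| > 0.3 × peak times
the checker area. For a radially symmetric Gaussian that threshold
traces the √(2 ln(1/0.3)) = 1.5518σ contour, so dividing the counted
area by 1.5518² converts it to the 1σ scale; on fine grids the two
measures agree within a few percent, and on 100 µm checkers within the
discretization error of a ~1.5-checker σ. The 0.3 fraction is the
default (0.35 is exposed as an option; only 0.3 is consistent with the
1.5518 correction).

## Flash and spot indices

PSTHs use 10 ms bins with no smoothing (peak = max bin; smoothing is
deliberately not applied and this is logged in the result kind). The RDI
takes peak rates in the first quarter (0.5 s) of the ON and OFF phases;
the spot bias takes peaks in the first 500 ms after bright- and
dark-spot onsets at the RF-center checker; both are
(R_ON − R_OFF)/(R_ON + R_OFF), undefined when both peaks are zero (an
error the pipeline converts to a flagged row).

## Convergence diagnostic

The STC-NC is recomputed on the first k spikes at 100-spike checkpoints
(cumulative second-moment updates, one eigendecomposition per
checkpoint) and projected onto the final estimate; a unit is converged
when every second-half checkpoint stays within 5% (absolute) of the
final projection of 1. At the default SNR, simulated cells cross
projection 0.8 at roughly 1.3–1.9 thousand spikes and 0.9 at 2.4–3.1
thousand, and 12 000-spike recordings are labelled converged; shorter
~5000-spike recordings often are not, which is the intended reading of
the criterion (it asks whether the *second half of the data* changed the
answer).

## Problem sizes and numerical choices

Default analyses run on 16×16 grids, 36 000-frame movies (~20 min), and
~5000 spikes per unit — sizes chosen so a 30-unit population
characterizes in well under a minute on one CPU while sitting in the
regime where the estimators' asymptotic behavior is visible. Dense
eigendecompositions are used throughout (M = 500 is trivial at this
scale; no iterative shortcut). Degenerate inputs (all-zero STA, empty
projection side, zero-rate PSTH pairs, non-symmetric moment matrices)
raise typed errors at the library level and become per-unit flags in the
pipeline. Known limitations: windows at the grid edge are zero-padded
(flagged, padded entries excluded from the ring noise estimate);
classification near the ±0.6 boundary inherits bias estimation noise;
and the dip test's uniform null is conservative for heavy-tailed
unimodal projections.
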