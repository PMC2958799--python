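# stcnc — non-centered spike-triggered covariance analysis

`stcnc` characterizes visual neurons — retinal ganglion cells recorded on a
multi-electrode array, in the typical use case — from their spike trains
under Gaussian white-noise checkerboard stimulation. Its core is the
**STC-NC** estimator: instead of the spike-triggered average (STA) or the
eigenvectors of the spike-triggered *covariance*, it takes the leading
eigenvector of the **non-centered second-moment matrix** of the
spike-triggered ensemble (STE),

```
M = (1/N) Σₙ sₙ sₙᵀ ,          sₙ = stimulus history preceding spike n,
```

whose top eigenvector maximizes the STE's second moment *about zero
contrast* rather than about its mean. For ON and OFF cells this direction
coincides with the STA; for ON-OFF cells — which fire to both luminance
increments and decrements, so their STA cancels toward zero — it still
recovers the linear filter of the LN (linear–nonlinear Poisson) cascade.
One estimator therefore maps all three classes.

Downstream, the toolkit:

- recovers the **static nonlinearity** N = L_STE / L_RSS from histograms of
  1-D projections of the STE and the raw stimulus set onto the filter,
  and summarizes it by the **bias** (P_ON − P_OFF)/(P_ON + P_OFF) ∈ [−1, 1];
  cells are labelled OFF (< −0.6), ON (> +0.6), or ON-OFF (between);
- tests **bimodality** of the 1-D STE projection with Hartigan's dip
  statistic and a uniform-bootstrap p-value (ON-OFF cells project
  bimodally, one lobe per response polarity);
- measures **RF-center size** by a rotated bivariate-Gaussian fit
  (1σ ellipse area = π·σₐ·σᵦ) and by counting checkers above 0.3× the peak,
  reconciled through the √(2·ln(1/0.3)) = 1.5518σ contour equivalence;
- computes full-field flash (**RDI**) and single-checker spot
  (**spot bias**) response indices;
- ships a seed-reproducible **stimulus generator** (truncated-Gaussian
  checkerboard, flash, spot) and an **LN-Poisson cell simulator** that
  provide ground truth for every estimator.

## Worked example

```python
import numpy as np
from stcnc import stimulus, synth, ensemble, moments

cfg = stimulus.StimulusConfig(grid_rows=16, grid_cols=16, seed=1)   # 100 um checkers, 33 ms frames
movie = stimulus.generate_white_noise(cfg, 36000)                    # ~20 min of stimulation
cell = synth.make_cell("ON_OFF", cfg, center_um=(850, 850), spatial_sigma_um=70)
train = synth.simulate_spikes(cell, movie, seed=2)

counts = ensemble.bin_spikes(train, movie.frame_times).counts
center = moments.find_center_from_energy(movie, counts, f=20)
ste = ensemble.build_ste(movie, counts, f=20, center=center, spatial=(5, 5))
sta = moments.compute_sta(ste)
stcnc = moments.stc_nc_filter(moments.compute_noncentered_moment(ste), ste)
```

Running `python examples/01_recover_onoff_filter.py` (the same analysis)
prints:

```
simulated 5120 spikes from a balanced ON-OFF cell
|<STA, true filter>|    = 0.041   (STA is destroyed by symmetry)
|<STC-NC, true filter>| = 0.934   (non-centered eigenvector recovers it)
STC-NC ring signal strength = 25.5 sigma (>= 6 counts as mappable)
```

The STA retains essentially no overlap with the ground-truth filter (0.04,
chance level in 500 dimensions), while the STC-NC eigenvector recovers it
at 0.93 from ~5000 spikes; the 25σ ring strength says the filter stands
far above the noise floor of the window border, so the unit passes the 6σ
mappability gate. `examples/02_classify_population.py` then classifies a
12-cell population: ON and OFF cells land at bias ±0.97 with unimodal
projections (dip p ≫ 0.05), ON-OFF cells at bias ≈ 0 with strongly bimodal
ones (dip p < 0.001), and every label matches ground truth. The remaining
examples measure RF sizes and the flash/spot indices.

A thin CLI wraps the same pipeline for batch use:
`stcnc simulate|characterize|flashspot|report --help`.

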