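"""Recover an ON-OFF cell's linear filter where the STA fails.

Simulates a balanced ON-OFF LN-Poisson cell on Gaussian white-noise
checkerboard, then estimates its filter two ways: the spike-triggered
average (which cancels, because bright and dark stimuli drive the cell
equally) and the leading eigenvector of the non-centered second moment
(STC-NC), which recovers it.
"""

import numpy as np

from stcnc import ensemble, moments, stimulus, synth

cfg = stimulus.StimulusConfig(grid_rows=16, grid_cols=16, seed=1)
movie = stimulus.generate_white_noise(cfg, 36000)  # ~20 min of recording

cell = synth.make_cell("ON_OFF", cfg, center_um=(850, 850), spatial_sigma_um=70)
train = synth.simulate_spikes(cell, movie, seed=2)
print(f"simulated {train.n_spikes} spikes from a balanced ON-OFF cell")

counts = ensemble.bin_spikes(train, movie.frame_times).counts
center = moments.find_center_from_energy(movie, counts, f=20)
ste = ensemble.build_ste(movie, counts, f=20, center=center, spatial=(5, 5))

sta = moments.compute_sta(ste)
stcnc = moments.stc_nc_filter(moments.compute_noncentered_moment(ste), ste)
truth = cell.filter.windowed_vector(center, (5, 5))

sta_overlap = abs(sta.vector / np.linalg.norm(sta.vector) @ truth)
stc_overlap = abs(stcnc.vector @ truth)
print(f"|<STA, true filter>|    = {sta_overlap:.3f}   (STA is destroyed by symmetry)")
print(f"|<STC-NC, true filter>| = {stc_overlap:.3f}   (non-centered eigenvector recovers it)")
print(f"STC-NC ring signal strength = {moments.stcnc_signal_strength(stcnc):.1f} sigma"
      " (>= 6 counts as mappable)")
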