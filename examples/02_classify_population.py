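"""Classify a mixed population of simulated retinal ganglion cells.

Builds 12 LN-Poisson cells (4 ON, 4 OFF, 4 ON-OFF), runs the end-to-end
pipeline (STA gate -> window -> STC-NC -> static nonlinearity -> bias ->
dip test -> label), and prints the classification table against ground
truth.  The bias thresholds are +/-0.6; the dip p-value flags bimodal
(ON-OFF type) projections.
"""

from stcnc import classify, pipeline, stimulus, synth
from stcnc.pipeline import PipelineParams

cfg = stimulus.StimulusConfig(grid_rows=16, grid_cols=16, seed=3)
movie = stimulus.generate_white_noise(cfg, 36000)
cells = synth.make_population(4, 4, 4, cfg, seed=4)
trains = [synth.simulate_spikes(c, movie, seed=10 + i) for i, c in enumerate(cells)]

results = pipeline.characterize_population(movie, trains, PipelineParams(seed=5))

print(f"{'unit':12s} {'true':7s} {'label':7s} {'bias':>6s} {'dip p':>6s} {'ring':>5s}")
for cell, res in zip(cells, results):
    print(
        f"{cell.id:12s} {cell.true_label:7s} {res.label:7s} "
        f"{res.bias:6.2f} {res.dip.p_value:6.3f} {res.stcnc_strength:5.1f}"
    )

labels = [classify.CellLabel(r.label) for r in results]
summary = classify.population_summary(labels)
print("\npopulation fractions over mappable cells:")
for k, v in summary["fractions"].items():
    print(f"  {k:7s} {100 * v:5.1f}%")
print("ON and OFF cells sit at |bias| near 1 with unimodal projections"
      " (high dip p); ON-OFF cells sit near 0 with bimodal ones (dip p < 0.05).")
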