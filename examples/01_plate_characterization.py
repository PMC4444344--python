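"""Characterize a promoter from microplate kinetics.

Simulates one plate experiment (a repressible promoter across an AHL dose
ladder, plus reference-promoter wells, medium blanks and a non-fluorescent
control), then runs the standard chain on every well: background
subtraction, exponential-window detection on OD 0.05-0.2, growth rate,
per-cell synthesis rate S_cell, and RPU against the reference promoter.
"""

import numpy as np

from luxrep import HillParams, pipeline, simulate

exp = simulate.simulate_repression_experiment(
    hill=HillParams(delta=0.05, vmax=2.0, km=2.0, eta=1.5),
    rpu_noise_sd=0.05, seed=1,
)
samples, references = pipeline.characterize_experiment(
    exp.samples, exp.references, exp.blanks, exp.control
)

ref = references[0]
print(f"reference well {ref.series.well_id}:")
print(f"  growth rate m   = {ref.growth.m:.5f} min^-1")
print(f"  doubling time   = {ref.growth.doubling_time:.1f} min")
print(f"  S_cell          = {ref.synthesis.s_cell_mean:.1f} AU min^-1 cell^-1")

print("\nAHL (nM)   mean RPU over replicates")
for ahl in sorted({s.series.ahl_nM for s in samples}):
    rpus = [s.rpu for s in samples if s.series.ahl_nM == ahl]
    print(f"{ahl:8.1f}   {np.mean(rpus):6.3f}")

# The RPU column traces the repression curve: ~2.05 RPU with no inducer
# (delta + V_MAX), half repression near K_M = 2 nM, and the basal activity
# delta ~ 0.05 RPU at full induction.
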