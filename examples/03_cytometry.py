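"""Single-cell promoter activity from flow-cytometry events.

Simulates log-binned event tables (sample, non-fluorescent control and
reference promoter), runs the fixed processing order — discard FL1 = 0,
convert channels to linear scale (4 decades / 4096 channels), rectangular
FSC/SSC percentile gate — and reports the background-subtracted mean,
cell-to-cell CV and single-cell RPU.
"""

from luxrep import cytometry, simulate
from luxrep.simulate import CytometryTruth

truth = CytometryTruth(log10_mean=2.7, log10_sd=0.2232, n_events=100_000, seed=5)
sample = cytometry.process_events(simulate.simulate_events(truth, sample_id="clone"))
control = cytometry.process_events(simulate.simulate_events(
    CytometryTruth(n_events=100_000, seed=6, zero_fraction=0.0),
    sample_id="TOP10", role="nonfluorescent_control", fluorescent=False,
))
reference = cytometry.process_events(simulate.simulate_events(
    CytometryTruth(log10_mean=2.7, log10_sd=0.2232, n_events=100_000, seed=7),
    sample_id="J23101", role="reference",
))

summary = cytometry.summarize_events(sample, control, reference)
print(f"events: {sample.n_input} acquired, {sample.n_discarded_zero} FL1=0 "
      f"discarded, {sample.n_gated_out} gated out, {summary.n_events} retained")
print(f"background-subtracted mean FL1 = {summary.mean_fl1:.1f}")
print(f"cell-to-cell CV = {summary.cv:.3f} (generator truth {truth.cv_true:.3f})")
print(f"single-cell RPU = {summary.rpu:.3f}")
print(f"bimodal: {cytometry.is_bimodal(sample.fl1_lin, seed=0)}")

# Well over 20,000 events survive processing; the CV of the log-normal
# population (~0.55, the typical cell-to-cell variability of these
# constructs) is recovered from the binned channels, and the clone measured
# against an identical-strength reference lands at RPU ~ 1.
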