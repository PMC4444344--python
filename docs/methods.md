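# Methods

This note records the models and procedures `luxrep` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the underlying
protocol leaves room.

## Plate kinetics

**Measurement model.** A well's raw OD600 is biomass plus a medium
background; raw fluorescence is reporter signal plus biomass-proportional
autofluorescence. Background subtraction therefore differs per channel:

* OD: the per-time-point arithmetic mean of the medium-blank wells is
  subtracted.
* Fluorescence: the non-fluorescent control culture's fluorescence is
  subtracted **OD-matched** — the control's fluorescence is linearly
  interpolated as a function of its own corrected OD and evaluated at the
  sample's corrected OD. Autofluorescence scales with biomass, not with
  wall-clock time, so OD-matching is the default; a time-matched variant is
  selectable (`fluor_mode="time_matched"`) and the variant used is stamped
  into provenance. Negative corrected values are clipped to 0 and counted
  per well.

**Exponential phase.** The window is the first maximal contiguous run of
time points whose corrected OD lies in the inclusive band [0.05, 0.2]
(thresholds configurable). The band is applied after blank subtraction.
A window below 4 points rejects the well outright rather than fitting a
too-short segment. Ties between equally long runs resolve to the earlier
one, keeping the choice deterministic.

**Estimators.** Growth rate *m* is the mean numeric time derivative of
ln(OD) over the window; doubling time is ln 2/*m*. The derivative is
central differences at interior points and one-sided two-point differences
at the series edges — the lowest-order scheme that is exact for linear
trends (so exact for ln OD of a pure exponential). The synthesis-rate
signal is (dF/dt)/OD per time point, with the derivative computed over the
full series so window-edge points use their true neighbours, then averaged
over the window to give *S*<sub>cell</sub> (AU min⁻¹ cell⁻¹).

**RPU.** RPU = *S*<sub>cell,x</sub>/*S*<sub>cell,ref</sub>, where the
reference bears BBa_J23101 and must match the sample on reporter, copy
context, promoter–RBS junction and acquisition gain (mismatch is an error
naming the key). The growth-rate-corrected RPU variant is deliberately
omitted: in the conditions this package targets, growth rates do not differ
measurably between constructs, and including the term changes nothing but
adds a noisy factor. RPU is invariant under common rescaling of sample and
reference fluorescence, which is what makes gain-matched acquisition
sufficient.

Time is minutes everywhere; indices are 0-based; windows half-open.

## Hill repression fits

The dose–response of a repressible promoter is modelled as
Y(A) = δ + V_MAX/(1+(A/K_M)^η) with all parameters ≥ 0 and η bounded to
[0.1, 10] by default. Fitting is unweighted least squares over **all
replicate points** (not replicate means) with `scipy.optimize.least_squares`
(TRF, bounds as above, tolerances 1e-12): the noise-variance estimate
σ² = RSS/(N−k) with k = 4 only makes sense when N counts raw points.
A = 0 evaluates to exactly δ+V_MAX; K_M = 0 is treated as the η-power limit
(δ for any A > 0).

**Initialization** (the underlying protocol is silent): δ₀ = min Y,
V_MAX₀ = max Y − min Y, K_M₀ = the AHL level whose mean response is nearest
half-repression, geometrically interpolated between the bracketing levels,
η₀ = 1. Curves spanning less than 2-fold are flagged `non-repressible`;
fewer than 5 AHL levels flags `few-levels`. Very steep fitted η (> 2) in
low-activity clones is a fitting artefact, which is why the η bounds are
configurable and wide rather than tight.

**Monte Carlo CV.** 10,000 synthetic datasets by default (tests and the
acceptance study use smaller depths; see below): i.i.d. N(0, σ²) noise
added to the fitted curve at the original AHL values, each refit with the
same initial parameters as the original fit, CV = sd/mean (ddof = 1) per
parameter over the refit distribution. Refits that fail to converge are
dropped and counted; a failure fraction above 10% is surfaced. σ² = 0 short
circuits to all-zero CVs — with zero noise every refit reproduces the
original parameters exactly, so the shortcut is the limit, not an
approximation.

## Cytometry

Events arrive as integer log-binned channels in 0–4095. Processing order is
fixed: **discard FL1 = 0 → linearize → FSC/SSC gate → summarize**. The
FL1 = 0 discard operates on the raw integer channel, before linearization
(channel 0 maps to linear 1.0, so the order does not change results, but
the contract is on the stored channel). The log→linear transfer is
10^(channel·decades/channels) with 4 decades over 4096 channels by default —
standard for this instrument class; the true instrument transfer is not
knowable from exported channels alone, so both knobs are configurable and
stamped into provenance. Downstream RPU ratios are only approximately
invariant to the decades choice because background subtraction breaks exact
scale invariance; this is recorded, not resolved.

Gating is a rectangular percentile gate, keeping events with FSC and SSC
each inside the sample's [5th, 95th] percentiles by default. The gate
removing > 95% of events is an error. CV uses the sample standard deviation
(n−1). Background subtraction removes the control's FL1 arithmetic mean;
CV is sd(sample FL1)/background-subtracted mean, so a bright sample over a
dim control is required for an accurate CV (the generator's default control
mean is two orders of magnitude below the signal, matching real
autofluorescence).

A conservative bimodality flag fits 1- vs 2-component Gaussian mixtures to
log10(FL1) and requires a ≥ 10-unit BIC win **and** ≥ 2 pooled-sd component
separation **and** ≥ 5% minor weight before calling a distribution bimodal;
population-level characterization is only meaningful for unimodal clones.

## Group statistics

For one promoter measured across conditions: one-way ANOVA on the replicate
RPUs; if non-significant (α = 0.05), no CV is reported. If significant, all
pairwise equal-variance t-tests at the Bonferroni threshold α/C(n,2);
conditions sorted by mean are chain-merged into sub-groups wherever the
adjacent pair is non-significant — deterministic and order-free under
non-transitive pairwise outcomes. The context CV is the small-sample
corrected CV·(1+1/(4N)) over the sub-group means (members averaged first);
when the post-hoc step finds no separation the CV is taken over all
condition means. N is the number of values entering the CV, and is
reported alongside.

Library summaries: fold range = max/min over members above detection;
mean spacing = mean of (a₍ᵢ₊₁₎ − aᵢ)/a₍ᵢ₊₁₎ over strength-sorted adjacent
pairs (a geometric alternative, (max/min)^(1/(n−1)) − 1, is available for
sensitivity checks; the definition used is recorded in the output).

## Promoter design

Promoters are stored as 5-nt −35 segment + 20-nt lux box + 5-nt −10
segment + proximal sequence; the invariant boundary bases (the A ending the
−35 hexamer, the T starting the −10 hexamer) belong to the lux box. The
consensus builder filters hexamer pairs violating that boundary constraint,
then takes the positionwise minimal IUPAC cover of the observed bases
(never N unless all four bases occur). Matching is case-insensitive and
strand-fixed — the library is defined on the sense strand. The shipped
consensus `YTKAY`/`AYWRT` spans exactly 8×8 = 64 promoters, and all 12
sequenced members fall inside that space. Primer assembly is plain
concatenation (cloning prefix + degenerate region + proximal + annealing
tail); melting temperature and amplicon-length checks are out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, so
that recovery tests are exact where they should be:

* OD: constant `od_init` through a lag, then exponential growth at rate *m*
  **hard-capped** at a carrying OD, plus the medium background. The cap
  keeps ln(OD) exactly linear inside the analysis band — so the estimator's
  ground truth is the generator's *m* — while the saturating tail still
  exercises window detection. A logistic tail was considered and rejected:
  its rate term *m*(1 − OD/K) is already ~10% below *m* inside [0.05, 0.2]
  at K ≈ 1, which would make "recover the generator's *m*" ill-posed.
* Fluorescence: biomass-proportional autofluorescence plus the cumulative
  trapezoidal integral of *S*<sub>cell</sub>·OD — the exact inverse of the
  estimator. Reporter maturation and dilution are ignored, as the estimator
  itself assumes. Replicate-level Hill scatter (`rpu_noise_sd`) is additive
  Gaussian on the RPU scale, clipped at zero (a per-cell synthesis rate
  cannot be negative), matching the homoscedastic-Gaussian assumption of
  the Monte Carlo CV procedure. Per-channel Gaussian measurement noise is
  also available.
* Default grid: 5-min sampling over 18 h. Default dose ladder: 0, 0.5, 1,
  2, 5, 10, 50, 100 nM — covering fully-activated through totally-repressed
  conditions around switch points of a few nM.
* Cytometry: log-normal single-cell signal (default log10 sd 0.2232,
  i.e. CV 0.55 — the typical cell-to-cell variability of these constructs)
  plus log-normal autofluorescence, binned with the inverse of the
  log→linear transfer; a configurable FL1 = 0 fraction is injected;
  ≥ 100,000 events by default.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: intrinsic gene-expression noise and plasmid
copy-number fluctuations, reporter maturation kinetics, growth burden
feedback, instrument drift, and heteroscedastic or non-Gaussian plate
noise. Recovery results certify the estimators against their own model
assumptions, not against biology.

Identical seeds give byte-identical outputs; every emitted dataset carries
its generating parameters in provenance.

## Problem sizes and statistical checks

The end-to-end recovery study simulates 3 replicates × 8 AHL levels at RPU
noise sd 0.05 and reports the median relative K_M error over 100 seeds
(observed ≈ 2%, bound 20%). Monte Carlo interval coverage is a fraction
whose true value sits 1–3% above the 90% bound (measured: δ 93%, V_MAX
92%, η 90.5% at 95% nominal — percentile intervals from a parametric
bootstrap undercover slightly), so it is estimated over 400 contiguous
seeds, bringing the binomial standard error to ~1.5%; shorter panels are
dominated by seed luck. The Monte Carlo depth for the coverage study is
300 refits per seed — interval endpoints are stable to well under the
margin being tested, at a fraction of the default depth's cost.

Degenerate inputs are rejected loudly rather than silently patched:
too-short windows, non-positive OD in a window, zero reference synthesis,
all-zero FL1, empty consensus input, out-of-range channels.
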