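"""End-to-end orchestration: simulated or measured plates down to Hill fits.

Thin glue over the per-well operations: characterize every sample and
reference well, convert per-well synthesis rates to RPU against the mean
reference, assemble the (AHL, RPU) repression curve and fit the Hill model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hill import HillFit, MonteCarloCV, RepressionCurve, fit_hill, mc_parameter_cv
from .plate import (
    GrowthResult, KineticSeries, SynthesisResult, characterize_well, compute_rpu,
)


@dataclass(frozen=True)
class WellResult:
    series: KineticSeries
    growth: GrowthResult
    synthesis: SynthesisResult
    rpu: Optional[float] = None


def characterize_experiment(
    samples: Sequence[KineticSeries],
    references: Sequence[KineticSeries],
    blanks: Sequence[KineticSeries],
    control: Optional[KineticSeries] = None,
    **well_kwargs,
) -> tuple[list[WellResult], list[WellResult]]:
    """Characterize all sample and reference wells of one experiment.

    Returns (sample results, reference results); each sample's RPU is its
    S_cell divided by the arithmetic mean S_cell of the reference wells.
    """
    ref_results = []
    for ref in references:
        corrected, growth, synth = characterize_well(ref, blanks, control, **well_kwargs)
        ref_results.append(WellResult(corrected, growth, synth, rpu=None))
    s_ref = float(np.mean([r.synthesis.s_cell_mean for r in ref_results]))
    if s_ref <= 0:
        raise ValueError(f"non-positive mean reference S_cell ({s_ref:.3g})")

    # metadata matching is enforced against the first reference well
    ref0 = ref_results[0]
    sample_results = []
    for well in samples:
        corrected, growth, synth = characterize_well(well, blanks, control, **well_kwargs)
        compute_rpu(synth, ref0.synthesis, corrected, ref0.series)  # raises on mismatch
        sample_results.append(
            WellResult(corrected, growth, synth, rpu=synth.s_cell_mean / s_ref)
        )
    return sample_results, ref_results


def repression_curve_from_results(
    results: Sequence[WellResult], promoter_id: str = "", context: str = ""
) -> RepressionCurve:
    """Assemble the (AHL, RPU) curve from characterized sample wells."""
    ahl = np.array([r.series.ahl_nM for r in results], dtype=float)
    rpu = np.array([r.rpu for r in results], dtype=float)
    rep = np.array([r.series.well_id for r in results])
    return RepressionCurve(ahl_nM=ahl, rpu=rpu, replicate=rep,
                           promoter_id=promoter_id, context=context)


@dataclass(frozen=True)
class RecoveryStudy:
    """Result of a seeded end-to-end parameter-recovery simulation study."""

    median_rel_error: dict[str, float]
    coverage95: dict[str, float]
    n_seeds: int
    mc_datasets: int


def parameter_recovery_study(
    true_params,
    n_seeds: int = 100,
    rpu_noise_sd: float = 0.05,
    n_replicates: int = 3,
    mc_datasets: int = 300,
    seed0: int = 0,
    mc_seed0: int = 100_000,
) -> RecoveryStudy:
    """Repeatedly simulate a repression experiment, run the full pipeline and
    fit, and score parameter recovery.

    Reports the median relative error per Hill parameter across seeds and,
    when ``mc_datasets`` > 0, the fraction of seeds whose central 95% Monte
    Carlo interval covers the true parameter value.
    """
    from .hill import PARAM_NAMES
    from .simulate import simulate_repression_experiment

    errors: dict[str, list[float]] = {p: [] for p in PARAM_NAMES}
    inside: dict[str, int] = {p: 0 for p in PARAM_NAMES}
    for i in range(n_seeds):
        exp = simulate_repression_experiment(
            hill=true_params, rpu_noise_sd=rpu_noise_sd,
            n_replicates=n_replicates, seed=seed0 + i,
        )
        curve, fit, _ = fit_experiment(
            exp.samples, exp.references, exp.blanks, exp.control
        )
        for p in PARAM_NAMES:
            tv = getattr(true_params, p)
            errors[p].append(abs(getattr(fit.params, p) - tv) / abs(tv))
        if mc_datasets:
            mc = mc_parameter_cv(
                fit, curve, n_datasets=mc_datasets, seed=mc_seed0 + i,
                keep_samples=True,
            )
            lo, hi = np.percentile(mc.samples, [2.5, 97.5], axis=0)
            for j, p in enumerate(PARAM_NAMES):
                tv = getattr(true_params, p)
                if lo[j] <= tv <= hi[j]:
                    inside[p] += 1
    return RecoveryStudy(
        median_rel_error={p: float(np.median(v)) for p, v in errors.items()},
        coverage95={p: inside[p] / n_seeds for p in inside} if mc_datasets else {},
        n_seeds=n_seeds,
        mc_datasets=mc_datasets,
    )


def fit_experiment(
    samples: Sequence[KineticSeries],
    references: Sequence[KineticSeries],
    blanks: Sequence[KineticSeries],
    control: Optional[KineticSeries] = None,
    mc_datasets: int = 0,
    mc_seed: int = 0,
    **well_kwargs,
) -> tuple[RepressionCurve, HillFit, Optional[MonteCarloCV]]:
    """Full chain: characterize wells → repression curve → Hill fit
    (→ Monte Carlo CV when ``mc_datasets`` > 0)."""
    sample_results, _ = characterize_experiment(
        samples, references, blanks, control, **well_kwargs
    )
    curve = repression_curve_from_results(sample_results)
    fit = fit_hill(curve)
    mc = mc_parameter_cv(fit, curve, mc_datasets, seed=mc_seed) if mc_datasets else None
    return curve, fit, mc
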