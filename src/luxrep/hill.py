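"""Hill repression curves and Monte Carlo parameter uncertainty.

The repressible promoters are modelled by the four-parameter Hill function

    Y(A) = delta + V_MAX / (1 + (A / K_M)**eta)

where Y is promoter activity in RPU, A the AHL concentration (nM), ``delta``
the basal activity in the fully repressed state, ``delta + V_MAX`` the
maximum activity in absence of AHL, ``K_M`` the switch point and ``eta`` the
Hill coefficient.  Parameters are estimated by unweighted least squares over
all replicate points.  Parameter uncertainty is quantified by a parametric
Monte Carlo: Gaussian noise with variance sigma^2 = RSS/(N - k) (k = 4) is
added to the fitted curve at the original AHL values, each synthetic dataset
is refitted with the same initial parameters, and the per-parameter
coefficient of variation is taken over the resulting distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

N_PARAMS = 4  # delta, vmax, km, eta
DEFAULT_ETA_BOUNDS = (0.1, 10.0)
DEFAULT_MC_DATASETS = 10_000

PARAM_NAMES = ("delta", "vmax", "km", "eta")


class HillError(ValueError):
    """Raised on invalid dose-response inputs or failed fits."""


@dataclass(frozen=True)
class HillParams:
    delta: float
    vmax: float
    km: float
    eta: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise HillError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.vmax, self.km, self.eta], dtype=float)


@dataclass(frozen=True)
class RepressionCurve:
    """(AHL, RPU) dose-response data for one promoter, replicates included."""

    ahl_nM: np.ndarray
    rpu: np.ndarray
    replicate: Optional[np.ndarray] = None
    promoter_id: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.ahl_nM, dtype=float)
        y = np.asarray(self.rpu, dtype=float)
        if a.shape != y.shape or a.ndim != 1:
            raise HillError("ahl_nM and rpu must be 1-D arrays of equal length")
        if np.any(a < 0):
            raise HillError("AHL concentrations must be >= 0")
        object.__setattr__(self, "ahl_nM", a)
        object.__setattr__(self, "rpu", y)

    def __len__(self) -> int:
        return len(self.ahl_nM)

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.ahl_nM))


@dataclass(frozen=True)
class HillFit:
    params: HillParams
    rss: float
    n: int
    k: int = N_PARAMS
    init: Optional[HillParams] = None
    flags: tuple[str, ...] = ()

    @property
    def sigma2(self) -> float:
        """Residual noise variance estimate RSS/(N - k)."""
        return self.rss / (self.n - self.k)


@dataclass(frozen=True)
class MonteCarloCV:
    """Per-parameter Monte Carlo summaries (mean, sd, CV = sd/mean)."""

    cv: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    n_datasets: int
    n_failed: int
    seed: int
    samples: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_datasets if self.n_datasets else 0.0


def hill_predict(params: HillParams, ahl) -> np.ndarray | float:
    """Evaluate the Hill repression function.

    At A = 0 this returns exactly delta + vmax.  The degenerate switch point
    K_M = 0 is handled as the eta-power limit: delta for any A > 0.
    """
    a = np.asarray(ahl, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if np.any(a < 0):
        raise HillError("AHL concentration must be >= 0")
    out = np.empty_like(a)
    if params.km == 0.0:
        out[:] = params.delta
        out[a == 0] = params.delta + params.vmax
    else:
        zero = a == 0
        out[zero] = params.delta + params.vmax
        nz = ~zero
        out[nz] = params.delta + params.vmax / (1.0 + (a[nz] / params.km) ** params.eta)
    return float(out[0]) if scalar else out


def default_init(curve: RepressionCurve) -> HillParams:
    """Heuristic starting point: delta0 = min Y, vmax0 = span of Y, K_M0 the
    AHL level whose mean response is nearest to half-repression
    (geometrically interpolated between the bracketing levels), eta0 = 1."""
    y = curve.rpu
    a = curve.ahl_nM
    delta0 = float(np.min(y))
    vmax0 = max(float(np.max(y) - np.min(y)), 1e-12)
    half = delta0 + vmax0 / 2.0

    levels = np.unique(a)
    means = np.array([np.mean(y[a == lv]) for lv in levels])
    pos = levels > 0
    if not np.any(pos):
        km0 = 1.0
    else:
        lv, mu = levels[pos], means[pos]
        # geometric interpolation between the levels bracketing half-repression
        below = mu <= half
        if below.any() and (~below).any():
            i_hi = int(np.argmax(below))  # first level at/under half (means decrease)
            i_lo = max(i_hi - 1, 0)
            if i_lo == i_hi or mu[i_lo] == mu[i_hi]:
                km0 = float(lv[i_hi])
            else:
                w = (mu[i_lo] - half) / (mu[i_lo] - mu[i_hi])
                km0 = float(np.exp((1 - w) * np.log(lv[i_lo]) + w * np.log(lv[i_hi])))
        else:
            km0 = float(lv[int(np.argmin(np.abs(mu - half)))])
    return HillParams(delta=delta0, vmax=vmax0, km=max(km0, 1e-9), eta=1.0)


def _residuals(theta: np.ndarray, a: np.ndarray, y: np.ndarray) -> np.ndarray:
    delta, vmax, km, eta = theta
    pred = np.empty_like(a)
    zero = a == 0
    pred[zero] = delta + vmax
    nz = ~zero
    pred[nz] = delta + vmax / (1.0 + (a[nz] / km) ** eta)
    return pred - y


def fit_hill(
    curve: RepressionCurve,
    init: Optional[HillParams] = None,
    eta_bounds: tuple[float, float] = DEFAULT_ETA_BOUNDS,
    flat_fold_threshold: float = 2.0,
) -> HillFit:
    """Least-squares fit of the Hill repression model over all replicate
    points (not replicate means).

    All parameters are bounded below by 0 (K_M by a tiny positive epsilon to
    keep the model defined); eta is constrained to ``eta_bounds``.  Curves
    whose response spans less than ``flat_fold_threshold``-fold are fitted
    anyway but flagged ``non-repressible``; curves with fewer than 5 AHL
    levels are flagged ``few-levels``.  The fit is deterministic given the
    data and the initial point.
    """
    a, y = curve.ahl_nM, curve.rpu
    n = len(curve)
    if n <= N_PARAMS:
        raise HillError(f"need more than {N_PARAMS} points, got {n}")
    flags: list[str] = []
    if curve.n_levels < 5:
        flags.append("few-levels")
    ymin, ymax = float(np.min(y)), float(np.max(y))
    if ymin <= 0 or ymax / max(ymin, 1e-300) < flat_fold_threshold:
        if ymax - ymin < 1e-12 * max(abs(ymax), 1.0) or (
            ymin > 0 and ymax / ymin < flat_fold_threshold
        ):
            flags.append("non-repressible")

    theta0 = (init or default_init(curve)).as_array()
    lo = np.array([0.0, 0.0, 1e-12, eta_bounds[0]])
    hi = np.array([np.inf, np.inf, np.inf, eta_bounds[1]])
    theta0 = np.clip(theta0, lo, hi)

    res = least_squares(
        _residuals, theta0, args=(a, y), bounds=(lo, hi),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
    )
    if not res.success:
        raise HillError(
            f"Hill fit did not converge (status {res.status}, "
            f"final residual {0.5 * float(res.cost):.3g})"
        )
    params = HillParams(*[float(v) for v in res.x])
    rss = float(np.sum(res.fun**2))
    return HillFit(
        params=params, rss=rss, n=n,
        init=HillParams(*[float(v) for v in theta0]), flags=tuple(flags),
    )


def mc_parameter_cv(
    fit: HillFit,
    curve: RepressionCurve,
    n_datasets: int = DEFAULT_MC_DATASETS,
    seed: int = 0,
    eta_bounds: tuple[float, float] = DEFAULT_ETA_BOUNDS,
    max_failure_fraction_warn: float = 0.10,
    keep_samples: bool = False,
) -> MonteCarloCV:
    """Monte Carlo CV of the Hill parameters.

    Generates ``n_datasets`` synthetic datasets by adding i.i.d. Gaussian
    noise of variance sigma^2 = RSS/(N-4) to the fitted curve at the original
    AHL values, refits each with the same initial parameters as the original
    fit, and reports the CV (sd/mean, ddof=1) of each parameter's
    distribution.  Refits that fail to converge are dropped and counted; a
    failure fraction above 10% is flagged in the result.
    """
    if fit.sigma2 < 0:
        raise HillError("sigma2 must be >= 0")
    sigma = float(np.sqrt(fit.sigma2))
    a = curve.ahl_nM
    base = hill_predict(fit.params, a)
    if sigma == 0.0:
        # zero noise: every refit reproduces the original parameters exactly
        zeros = {p: 0.0 for p in PARAM_NAMES}
        means = {p: getattr(fit.params, p) for p in PARAM_NAMES}
        return MonteCarloCV(cv=zeros, mean=means, sd=zeros, n_datasets=n_datasets,
                            n_failed=0, seed=seed)

    rng = np.random.default_rng(seed)
    theta0 = (fit.init or fit.params).as_array()
    lo = np.array([0.0, 0.0, 1e-12, eta_bounds[0]])
    hi = np.array([np.inf, np.inf, np.inf, eta_bounds[1]])
    theta0 = np.clip(theta0, lo, hi)

    draws = np.empty((n_datasets, N_PARAMS))
    n_ok = 0
    n_failed = 0
    for _ in range(n_datasets):
        y_syn = base + rng.normal(0.0, sigma, size=len(a))
        res = least_squares(
            _residuals, theta0, args=(a, y_syn), bounds=(lo, hi),
            method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=500,
        )
        if res.success:
            draws[n_ok] = res.x
            n_ok += 1
        else:
            n_failed += 1
    if n_ok == 0:
        raise HillError("all Monte Carlo refits failed")
    draws = draws[:n_ok]
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if n_ok > 1 else np.zeros(N_PARAMS)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), 0.0)
    return MonteCarloCV(
        cv=dict(zip(PARAM_NAMES, map(float, cv))),
        mean=dict(zip(PARAM_NAMES, map(float, mean))),
        sd=dict(zip(PARAM_NAMES, map(float, sd))),
        n_datasets=n_datasets,
        n_failed=n_failed,
        seed=seed,
        samples=draws if keep_samples else None,
    )
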