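"""Microplate kinetic analysis: background subtraction, exponential-phase
detection, growth rate, per-cell synthesis rate and Relative Promoter Units.

The processing chain mirrors standard promoter-characterization practice for
96-well kinetic reads of OD600 and bulk fluorescence:

1. subtract the medium blank from OD and the non-fluorescent control's
   autofluorescence from the reporter signal;
2. locate the exponential growth phase as the OD band [0.05, 0.2];
3. growth rate ``m`` = mean numeric time derivative of ln(OD) in that window,
   doubling time = ln(2)/m;
4. per-cell synthesis rate ``S_cell`` = d(fluorescence)/dt divided by OD,
   averaged over the window (AU min^-1 cell^-1);
5. RPU = S_cell of the culture of interest divided by S_cell of the culture
   bearing the reference promoter BBa_J23101 measured under matched
   conditions (reporter, copy context, promoter-RBS junction, gain).

All times are minutes; windows are half-open 0-based index ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Role = Literal["sample", "medium_blank", "nonfluorescent_control", "reference"]

#: lower / upper OD600 bounds of the exponential growth phase
OD_BAND: tuple[float, float] = (0.05, 0.2)
#: minimum number of time points required inside the OD band
MIN_WINDOW_POINTS = 4


class PlateError(ValueError):
    """Raised on contract violations in the plate-kinetics pipeline."""


class NoExponentialWindow(PlateError):
    """Raised when a well has too few points inside the OD band."""


@dataclass(frozen=True)
class KineticSeries:
    """One well's kinetic time course with its acquisition metadata.

    ``time`` is in minutes and strictly increasing; ``od`` and ``fluor`` are
    the raw (or, after :func:`subtract_background`, corrected) OD600 and
    fluorescence readings on the same grid.
    """

    time: np.ndarray
    od: np.ndarray
    fluor: np.ndarray
    well_id: str
    role: Role = "sample"
    reporter: str = "RFP"
    gain: float = 1.0
    copy_context: str = "LC"
    junction: str = "TACTAGTG"
    ahl_nM: Optional[float] = None
    promoter: Optional[str] = None
    background_subtracted: bool = False
    #: processing notes (clip counts, subtraction variant) accumulated downstream
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        od = np.asarray(self.od, dtype=float)
        fl = np.asarray(self.fluor, dtype=float)
        if not (len(t) == len(od) == len(fl)):
            raise PlateError(
                f"well {self.well_id}: time/od/fluor lengths differ "
                f"({len(t)}/{len(od)}/{len(fl)})"
            )
        if len(t) < 2:
            raise PlateError(f"well {self.well_id}: need at least 2 time points")
        if np.any(np.diff(t) <= 0):
            raise PlateError(f"well {self.well_id}: time not strictly increasing")
        if self.gain <= 0:
            raise PlateError(f"well {self.well_id}: gain must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od", od)
        object.__setattr__(self, "fluor", fl)

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class Window:
    """Half-open index range [start, end) into a :class:`KineticSeries`."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PlateError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class GrowthResult:
    """Exponential growth rate ``m`` (min^-1) and doubling time ln(2)/m (min)."""

    m: float
    doubling_time: float
    window: Window
    well_id: str = ""


@dataclass(frozen=True)
class SynthesisResult:
    """Per-cell synthesis rate S_cell averaged over the exponential window."""

    s_cell_mean: float
    s_cell_series: np.ndarray
    window: Window
    well_id: str = ""


@dataclass(frozen=True)
class RPUValue:
    """Relative Promoter Units: S_cell ratio against the matched reference."""

    value: float
    sample_id: str
    reference_id: str
    matched_keys: tuple[str, ...] = ("reporter", "copy_context", "junction", "gain")


def _derivative(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Numeric time derivative: central differences at interior points,
    one-sided two-point differences at the edges (np.gradient)."""
    return np.gradient(np.asarray(y, dtype=float), np.asarray(t, dtype=float))


def subtract_background(
    sample: KineticSeries,
    blanks: Sequence[KineticSeries],
    control: Optional[KineticSeries] = None,
    fluor_mode: Literal["od_matched", "time_matched"] = "od_matched",
) -> KineticSeries:
    """Background-subtract one well.

    OD: the per-time-point arithmetic mean of the medium blanks is subtracted.
    Fluorescence: the non-fluorescent control's signal is subtracted, by
    default evaluated at the sample's corrected OD (linear interpolation of
    control fluorescence versus control corrected OD) because
    autofluorescence scales with biomass; ``fluor_mode="time_matched"``
    subtracts the control read at the same time point instead.

    Negative corrected values are clipped to 0 and counted in provenance.
    All series must share the sample's time grid.
    """
    if not blanks:
        raise PlateError("empty blank set")
    for b in blanks:
        if b.role != "medium_blank":
            raise PlateError(f"well {b.well_id} passed as blank has role {b.role!r}")
        if len(b) != len(sample) or not np.allclose(b.time, sample.time):
            raise PlateError(
                f"blank {b.well_id} time grid does not match sample {sample.well_id}"
            )
    blank_od = np.mean([b.od for b in blanks], axis=0)
    od_corr = sample.od - blank_od

    if control is not None:
        if control.role != "nonfluorescent_control":
            raise PlateError(
                f"well {control.well_id} passed as control has role {control.role!r}"
            )
        if len(control) != len(sample) or not np.allclose(control.time, sample.time):
            raise PlateError(
                f"control {control.well_id} time grid does not match sample "
                f"{sample.well_id}"
            )
        ctrl_od = control.od - blank_od
        if fluor_mode == "od_matched":
            order = np.argsort(ctrl_od)
            ctrl_fluor_at_od = np.interp(od_corr, ctrl_od[order], control.fluor[order])
            fluor_corr = sample.fluor - ctrl_fluor_at_od
        elif fluor_mode == "time_matched":
            fluor_corr = sample.fluor - control.fluor
        else:  # pragma: no cover - guarded by Literal type
            raise PlateError(f"unknown fluor_mode {fluor_mode!r}")
    else:
        fluor_corr = sample.fluor.copy()

    od_clipped = int(np.sum(od_corr < 0))
    fl_clipped = int(np.sum(fluor_corr < 0))
    if od_clipped or fl_clipped:
        logger.warning(
            "well %s: clipped %d negative OD and %d negative fluorescence values",
            sample.well_id, od_clipped, fl_clipped,
        )
    prov = dict(sample.provenance)
    prov.update(
        background_mode=fluor_mode,
        n_blanks=len(blanks),
        control_well=control.well_id if control is not None else None,
        od_values_clipped=od_clipped,
        fluor_values_clipped=fl_clipped,
    )
    return replace(
        sample,
        od=np.clip(od_corr, 0.0, None),
        fluor=np.clip(fluor_corr, 0.0, None),
        background_subtracted=True,
        provenance=prov,
    )


def exponential_window(
    series: KineticSeries,
    od_lo: float = OD_BAND[0],
    od_hi: float = OD_BAND[1],
    min_points: int = MIN_WINDOW_POINTS,
) -> Window:
    """Locate the exponential growth phase as the first maximal contiguous run
    of points whose (background-subtracted) OD lies in [od_lo, od_hi].

    Raises :class:`NoExponentialWindow` when fewer than ``min_points`` points
    fall in the band.
    """
    if not od_lo < od_hi:
        raise PlateError(f"od_lo ({od_lo}) must be below od_hi ({od_hi})")
    in_band = (series.od >= od_lo) & (series.od <= od_hi)
    # first maximal contiguous run of True
    best: Optional[tuple[int, int]] = None
    i = 0
    n = len(in_band)
    while i < n:
        if in_band[i]:
            j = i
            while j < n and in_band[j]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j
        else:
            i += 1
    if best is None or (best[1] - best[0]) < min_points:
        found = 0 if best is None else best[1] - best[0]
        raise NoExponentialWindow(
            f"well {series.well_id}: no exponential window — {found} point(s) with "
            f"OD in [{od_lo}, {od_hi}], need ≥ {min_points}"
        )
    return Window(best[0], best[1])


def growth_rate(series: KineticSeries, window: Window) -> GrowthResult:
    """Growth rate as the mean numeric time derivative of ln(OD) inside the
    exponential window; doubling time = ln(2)/m."""
    if window.end > len(series):
        raise PlateError(f"window {window} exceeds series length {len(series)}")
    od = series.od[window.slice]
    t = series.time[window.slice]
    if np.any(od <= 0):
        raise PlateError(f"well {series.well_id}: non-positive OD inside window")
    m = float(np.mean(_derivative(np.log(od), t)))
    if m <= 0:
        raise PlateError(f"well {series.well_id}: non-growing (m = {m:.3g} min^-1)")
    return GrowthResult(m=m, doubling_time=float(np.log(2) / m),
                        window=window, well_id=series.well_id)


def synthesis_rate(series: KineticSeries, window: Window) -> SynthesisResult:
    """Per-cell synthesis rate: dF/dt divided by OD, averaged over the window.

    The derivative is taken over the full series (so window-edge points use
    their true neighbours), then restricted to the window for averaging.
    """
    if window.end > len(series):
        raise PlateError(f"window {window} exceeds series length {len(series)}")
    od_win = series.od[window.slice]
    if np.any(od_win == 0):
        raise PlateError(f"well {series.well_id}: zero OD inside window")
    dfdt = _derivative(series.fluor, series.time)
    s_cell = dfdt[window.slice] / od_win
    return SynthesisResult(
        s_cell_mean=float(np.mean(s_cell)),
        s_cell_series=s_cell,
        window=window,
        well_id=series.well_id,
    )


MATCHED_KEYS = ("reporter", "copy_context", "junction", "gain")


def compute_rpu(
    sample: SynthesisResult,
    reference: SynthesisResult,
    sample_meta: KineticSeries,
    reference_meta: KineticSeries,
) -> RPUValue:
    """Relative Promoter Units: sample S_cell over reference S_cell.

    The reference must match the sample on reporter, copy context,
    promoter-RBS junction and acquisition gain; any mismatch raises naming
    the offending key. Growth-rate correction is deliberately omitted.
    """
    for key in MATCHED_KEYS:
        sv, rv = getattr(sample_meta, key), getattr(reference_meta, key)
        if sv != rv:
            raise PlateError(
                f"{key} mismatch between sample {sample_meta.well_id} ({sv!r}) "
                f"and reference {reference_meta.well_id} ({rv!r})"
            )
    if reference.s_cell_mean <= 0:
        raise PlateError(
            f"reference {reference.well_id}: non-positive S_cell "
            f"({reference.s_cell_mean:.3g})"
        )
    return RPUValue(
        value=sample.s_cell_mean / reference.s_cell_mean,
        sample_id=sample.well_id,
        reference_id=reference.well_id,
        matched_keys=MATCHED_KEYS,
    )


def characterize_well(
    sample: KineticSeries,
    blanks: Sequence[KineticSeries],
    control: Optional[KineticSeries] = None,
    od_lo: float = OD_BAND[0],
    od_hi: float = OD_BAND[1],
    min_points: int = MIN_WINDOW_POINTS,
    fluor_mode: Literal["od_matched", "time_matched"] = "od_matched",
) -> tuple[KineticSeries, GrowthResult, SynthesisResult]:
    """Run the full per-well chain: subtract → window → growth → synthesis."""
    corrected = subtract_background(sample, blanks, control, fluor_mode=fluor_mode)
    window = exponential_window(corrected, od_lo, od_hi, min_points)
    growth = growth_rate(corrected, window)
    synth = synthesis_rate(corrected, window)
    return corrected, growth, synth
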