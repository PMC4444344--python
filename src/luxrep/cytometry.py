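"""Flow-cytometry event processing for single-cell promoter activity.

Events arrive as log-binned integer channel values (FSC, SSC, FL1) in
0-4095.  Processing follows the fixed order: discard FL1 = 0 events,
convert channels to linear scale (``10**(channel * decades / channels)``,
default 4 decades over 4096 channels), rectangular percentile gating on
FSC/SSC, then background subtraction of the non-fluorescent control's FL1
arithmetic mean.  Single-cell RPU is the ratio of background-subtracted FL1
means against the reference-promoter sample; cell-to-cell variability is the
CV (sd/mean, sample sd) of the FL1 distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.mixture import GaussianMixture

CHANNEL_MAX = 4095
DEFAULT_DECADES = 4.0
DEFAULT_CHANNELS = 4096
DEFAULT_GATE_PERCENTILES = (5.0, 95.0)


class CytometryError(ValueError):
    """Raised on contract violations in the cytometry pipeline."""


@dataclass(frozen=True)
class EventTable:
    """Raw log-binned events: integer channels in [0, 4095] per event."""

    fsc: np.ndarray
    ssc: np.ndarray
    fl1: np.ndarray
    sample_id: str = ""
    role: str = "sample"
    n_discarded_zero: int = 0

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("fsc", "ssc", "fl1"):
            a = np.asarray(getattr(self, name))
            if not np.issubdtype(a.dtype, np.integer):
                if not np.allclose(a, np.round(a)):
                    raise CytometryError(f"{name}: channel values must be integers")
                a = np.round(a).astype(np.int64)
            if a.size and (a.min() < 0 or a.max() > CHANNEL_MAX):
                raise CytometryError(
                    f"{name}: channel values outside [0, {CHANNEL_MAX}] "
                    f"(min {a.min()}, max {a.max()})"
                )
            arrs[name] = a.astype(np.int64)
        if not (len(arrs["fsc"]) == len(arrs["ssc"]) == len(arrs["fl1"])):
            raise CytometryError("fsc/ssc/fl1 must have equal lengths")
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return len(self.fl1)


@dataclass(frozen=True)
class LinearEvents:
    """Linear-scale events plus the processing provenance counts."""

    fsc_lin: np.ndarray
    ssc_lin: np.ndarray
    fl1_lin: np.ndarray
    sample_id: str = ""
    role: str = "sample"
    decades: float = DEFAULT_DECADES
    channels: int = DEFAULT_CHANNELS
    n_input: int = 0
    n_discarded_zero: int = 0
    n_gated_out: int = 0
    gate_bounds: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.fl1_lin)

    @property
    def n_retained(self) -> int:
        return len(self)


@dataclass(frozen=True)
class SingleCellSummary:
    mean_fl1: float
    cv: float
    n_events: int
    rpu: Optional[float] = None
    sample_id: str = ""
    reference_id: Optional[str] = None
    flags: tuple[str, ...] = ()


def discard_zero_fl1(events: EventTable) -> EventTable:
    """Drop events whose raw FL1 channel is 0 (off-scale/empty events)."""
    keep = events.fl1 >= 1
    n_drop = int(np.sum(~keep))
    if not np.any(keep):
        raise CytometryError(f"sample {events.sample_id}: all events have FL1 = 0")
    return replace(
        events,
        fsc=events.fsc[keep], ssc=events.ssc[keep], fl1=events.fl1[keep],
        n_discarded_zero=events.n_discarded_zero + n_drop,
    )


def channel_to_linear(
    channel, decades: float = DEFAULT_DECADES, channels: int = DEFAULT_CHANNELS
):
    """Log-bin to linear transfer: linear = 10**(channel * decades / channels)."""
    if decades <= 0:
        raise CytometryError(f"decades must be positive, got {decades}")
    return np.power(10.0, np.asarray(channel, dtype=float) * decades / channels)


def linear_to_channel(
    linear, decades: float = DEFAULT_DECADES, channels: int = DEFAULT_CHANNELS
) -> np.ndarray:
    """Inverse binning: channel = round(channels * log10(linear) / decades),
    clipped into [0, channels - 1]."""
    x = np.asarray(linear, dtype=float)
    with np.errstate(divide="ignore"):
        ch = np.round(channels * np.log10(np.maximum(x, 1e-300)) / decades)
    return np.clip(ch, 0, channels - 1).astype(np.int64)


def linearize(
    events: EventTable,
    decades: float = DEFAULT_DECADES,
    channels: int = DEFAULT_CHANNELS,
) -> LinearEvents:
    """Convert all three log-binned channels to linear scale."""
    return LinearEvents(
        fsc_lin=channel_to_linear(events.fsc, decades, channels),
        ssc_lin=channel_to_linear(events.ssc, decades, channels),
        fl1_lin=channel_to_linear(events.fl1, decades, channels),
        sample_id=events.sample_id,
        role=events.role,
        decades=decades,
        channels=channels,
        n_input=len(events) + events.n_discarded_zero,
        n_discarded_zero=events.n_discarded_zero,
    )


def gate_fsc_ssc(
    events: LinearEvents,
    percentiles: tuple[float, float] = DEFAULT_GATE_PERCENTILES,
    max_removed_fraction: float = 0.95,
) -> LinearEvents:
    """Rectangular scatter gate: keep events whose FSC and SSC each lie within
    the sample's [lo, hi] percentile bounds (default [5th, 95th])."""
    lo, hi = percentiles
    if not 0 <= lo < hi <= 100:
        raise CytometryError(f"bad gate percentiles {percentiles}")
    fsc_b = np.percentile(events.fsc_lin, [lo, hi])
    ssc_b = np.percentile(events.ssc_lin, [lo, hi])
    keep = (
        (events.fsc_lin >= fsc_b[0]) & (events.fsc_lin <= fsc_b[1])
        & (events.ssc_lin >= ssc_b[0]) & (events.ssc_lin <= ssc_b[1])
    )
    n_out = int(np.sum(~keep))
    if len(events) and n_out / len(events) > max_removed_fraction:
        raise CytometryError(
            f"sample {events.sample_id}: gate removed "
            f"{n_out}/{len(events)} events (> {max_removed_fraction:.0%})"
        )
    return replace(
        events,
        fsc_lin=events.fsc_lin[keep],
        ssc_lin=events.ssc_lin[keep],
        fl1_lin=events.fl1_lin[keep],
        n_gated_out=events.n_gated_out + n_out,
        gate_bounds={
            "percentiles": (lo, hi),
            "fsc": (float(fsc_b[0]), float(fsc_b[1])),
            "ssc": (float(ssc_b[0]), float(ssc_b[1])),
        },
    )


def summarize_events(
    sample: LinearEvents,
    control: LinearEvents,
    reference: Optional[LinearEvents] = None,
) -> SingleCellSummary:
    """Background-subtracted FL1 mean, cell-to-cell CV and (optionally) RPU.

    The control's FL1 arithmetic mean is subtracted from the sample's FL1
    mean.  CV = sample sd of FL1 (ddof=1) over the background-subtracted
    mean.  RPU = sample mean over the reference's background-subtracted mean.
    """
    if (sample.decades, sample.channels) != (control.decades, control.channels):
        raise CytometryError("control processed with different decades/channels")
    bg = float(np.mean(control.fl1_lin))
    mean_fl1 = float(np.mean(sample.fl1_lin)) - bg
    flags: list[str] = []
    if mean_fl1 <= 0:
        flags.append("non-fluorescent")
        cv = float("nan")
    else:
        cv = float(np.std(sample.fl1_lin, ddof=1)) / mean_fl1
    rpu = None
    ref_id = None
    if reference is not None:
        ref_mean = float(np.mean(reference.fl1_lin)) - bg
        if ref_mean <= 0:
            raise CytometryError(
                f"reference {reference.sample_id}: non-positive "
                f"background-subtracted FL1 mean"
            )
        rpu = max(mean_fl1, 0.0) / ref_mean
        ref_id = reference.sample_id
    return SingleCellSummary(
        mean_fl1=mean_fl1, cv=cv, n_events=len(sample), rpu=rpu,
        sample_id=sample.sample_id, reference_id=ref_id, flags=tuple(flags),
    )


def process_events(
    events: EventTable,
    decades: float = DEFAULT_DECADES,
    channels: int = DEFAULT_CHANNELS,
    gate_percentiles: tuple[float, float] = DEFAULT_GATE_PERCENTILES,
) -> LinearEvents:
    """Standard chain: discard FL1=0 → linearize → FSC/SSC gate."""
    return gate_fsc_ssc(
        linearize(discard_zero_fl1(events), decades, channels), gate_percentiles
    )


def is_bimodal(
    fl1_lin: np.ndarray,
    seed: int = 0,
    bic_margin: float = 10.0,
    min_separation_sd: float = 2.0,
    min_weight: float = 0.05,
) -> bool:
    """Flag a fluorescence distribution as bimodal.

    Fits 1- and 2-component Gaussian mixtures to log10(FL1) and calls the
    distribution bimodal only when the 2-component model wins by more than
    ``bic_margin`` BIC units AND its components are separated by at least
    ``min_separation_sd`` pooled standard deviations with both weights above
    ``min_weight``.  Conservative by design: population measurements are
    meaningful only for unimodal clones.
    """
    x = np.log10(np.asarray(fl1_lin, dtype=float)).reshape(-1, 1)
    if len(x) < 20:
        raise CytometryError("too few events for a modality check")
    gm1 = GaussianMixture(1, random_state=seed).fit(x)
    gm2 = GaussianMixture(2, random_state=seed, n_init=3).fit(x)
    if gm2.bic(x) >= gm1.bic(x) - bic_margin:
        return False
    mu = gm2.means_.ravel()
    sd = np.sqrt(gm2.covariances_.ravel())
    w = gm2.weights_.ravel()
    sep = abs(mu[0] - mu[1]) / np.sqrt(np.mean(sd**2))
    return bool(sep >= min_separation_sd and w.min() >= min_weight)
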