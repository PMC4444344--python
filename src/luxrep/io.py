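"""File formats and run configuration.

* Tidy plate CSV: one row per (time, well, channel) with columns
  ``time_min, well, channel, value`` (channels ``od600|rfp|gfp``), plus a
  well-metadata CSV (``well, role, promoter, reporter, copy_context,
  junction, gain, ahl_nM``).
* Cytometry events: CSV with integer columns ``fsc, ssc, fl1`` (0-4095), or
  FCS 2.0/3.0 list-mode files with integer or float data.  The FCS reader
  is deliberately minimal (uncompensated list mode, the only layout these
  instruments export); parameter names are mapped to FSC/SSC/FL1 via a
  configurable alias table.
* Results: plain JSON with full provenance.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cytometry import (
    CHANNEL_MAX, DEFAULT_CHANNELS, DEFAULT_DECADES, DEFAULT_GATE_PERCENTILES,
    EventTable,
)
from .plate import KineticSeries, MIN_WINDOW_POINTS, OD_BAND

PathLike = Union[str, Path]

PLATE_COLUMNS = ("time_min", "well", "channel", "value")
FLUOR_CHANNELS = ("rfp", "gfp")


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """All tunable analysis parameters with their standard defaults."""

    od_lo: float = OD_BAND[0]
    od_hi: float = OD_BAND[1]
    min_window_points: int = MIN_WINDOW_POINTS
    background_mode: str = "od_matched"      # or "time_matched"
    mc_datasets: int = 10_000
    seed: int = 20150526
    eta_bounds: tuple[float, float] = (0.1, 10.0)
    decades: float = DEFAULT_DECADES
    channels: int = DEFAULT_CHANNELS
    gate_percentiles: tuple[float, float] = DEFAULT_GATE_PERCENTILES
    alpha: float = 0.05
    spacing_definition: str = "adjacent-relative"
    output_dir: str = "results"

    @classmethod
    def from_json(cls, path: PathLike) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("eta_bounds", "gate_percentiles"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# Tidy plate CSV

def write_plate(
    series: Sequence[KineticSeries], csv_path: PathLike, metadata_path: PathLike
) -> None:
    """Write wells as tidy plate CSV plus a metadata table."""
    rows = []
    meta = []
    for s in series:
        channel = s.reporter.lower() if s.reporter.lower() in FLUOR_CHANNELS else "rfp"
        for t, od, fl in zip(s.time, s.od, s.fluor):
            rows.append((t, s.well_id, "od600", od))
            rows.append((t, s.well_id, channel, fl))
        meta.append(
            dict(well=s.well_id, role=s.role, promoter=s.promoter or "",
                 reporter=s.reporter, copy_context=s.copy_context,
                 junction=s.junction, gain=s.gain,
                 ahl_nM="" if s.ahl_nM is None else s.ahl_nM)
        )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(csv_path, index=False)
    pd.DataFrame(meta).to_csv(metadata_path, index=False)


def read_plate(csv_path: PathLike, metadata_path: PathLike) -> list[KineticSeries]:
    """Read the tidy plate CSV joined to its metadata table."""
    df = pd.read_csv(csv_path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"plate CSV missing column(s) {sorted(missing)}")
    dup = df.duplicated(subset=["time_min", "well", "channel"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicate (time, well, channel) row: "
            f"({row.time_min}, {row.well}, {row.channel})"
        )
    bad = ~df["channel"].isin(("od600",) + FLUOR_CHANNELS)
    if bad.any():
        raise FormatError(f"unknown channel(s) {sorted(df.loc[bad, 'channel'].unique())}")

    meta = pd.read_csv(metadata_path).set_index("well")
    out: list[KineticSeries] = []
    unknown_wells = sorted(set(df["well"].unique()) - set(meta.index))
    if unknown_wells:
        raise FormatError(f"wells missing from metadata: {unknown_wells}")
    for well, g in df.groupby("well", sort=False):
        info = meta.loc[well]
        od = g[g.channel == "od600"].sort_values("time_min")
        reporter = str(info.get("reporter", "RFP"))
        fl_channel = reporter.lower() if reporter.lower() in FLUOR_CHANNELS else None
        fl_candidates = [c for c in FLUOR_CHANNELS if (g.channel == c).any()]
        if fl_channel is None:
            if len(fl_candidates) != 1:
                raise FormatError(
                    f"well {well}: cannot infer fluorescence channel from "
                    f"{fl_candidates} with reporter {reporter!r}"
                )
            fl_channel = fl_candidates[0]
        fl = g[g.channel == fl_channel].sort_values("time_min")
        if len(od) == 0 or len(fl) == 0:
            raise FormatError(f"well {well}: missing od600 or {fl_channel} rows")
        if not np.array_equal(od.time_min.values, fl.time_min.values):
            raise FormatError(f"well {well}: od600 and {fl_channel} time grids differ")
        ahl = info.get("ahl_nM", None)
        ahl = None if (ahl is None or (isinstance(ahl, float) and np.isnan(ahl)) or ahl == "") else float(ahl)
        out.append(
            KineticSeries(
                time=od.time_min.values, od=od.value.values, fluor=fl.value.values,
                well_id=str(well), role=str(info["role"]),
                promoter=str(info.get("promoter", "")) or None,
                reporter=reporter,
                copy_context=str(info.get("copy_context", "LC")),
                junction=str(info.get("junction", "TACTAGTG")),
                gain=float(info.get("gain", 1.0)),
                ahl_nM=ahl,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cytometry events: CSV and FCS

EVENT_COLUMNS = ("fsc", "ssc", "fl1")

#: default instrument-name aliases for the three channels used here
DEFAULT_PARAM_ALIASES: dict[str, tuple[str, ...]] = {
    "fsc": ("FSC", "FS", "FSC-H", "FSC-A", "FS Lin"),
    "ssc": ("SSC", "SS", "SSC-H", "SSC-A", "SS Lin"),
    "fl1": ("FL1", "FL1-H", "FL1-A", "GFP", "FITC"),
}


def write_events_csv(events: EventTable, path: PathLike) -> None:
    pd.DataFrame(
        {"fsc": events.fsc, "ssc": events.ssc, "fl1": events.fl1}
    ).to_csv(path, index=False)


def read_events_csv(path: PathLike, sample_id: str = "", role: str = "sample") -> EventTable:
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events CSV missing column(s) {sorted(missing)}")
    return EventTable(
        fsc=df.fsc.values, ssc=df.ssc.values, fl1=df.fl1.values,
        sample_id=sample_id or Path(path).stem, role=role,
    )


def _parse_fcs_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FormatError("empty FCS TEXT segment")
    delim = segment[0:1]
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FormatError("FCS TEXT segment has an odd number of tokens")
    return {
        parts[i].decode("ascii", "replace").strip().upper():
        parts[i + 1].decode("ascii", "replace").strip()
        for i in range(0, len(parts), 2)
    }


def read_fcs(
    path: PathLike,
    sample_id: str = "",
    role: str = "sample",
    param_aliases: Optional[dict[str, tuple[str, ...]]] = None,
) -> EventTable:
    """Read a list-mode FCS 2.0/3.0 file into an :class:`EventTable`.

    Supports integer ($DATATYPE I, 8/16/32-bit) and float (F/D) data in
    either byte order.  Parameter names ($PnN / $PnS) are mapped to
    fsc/ssc/fl1 through ``param_aliases`` (case-insensitive exact match).
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise FormatError(f"not an FCS file (version field {version!r})")
    try:
        text_start, text_end = int(raw[10:18]), int(raw[18:26])
        data_start, data_end = int(raw[26:34]), int(raw[34:42])
    except ValueError as e:
        raise FormatError(f"bad FCS header offsets: {e}") from None
    text = _parse_fcs_text(raw[text_start:text_end + 1])
    if data_start == 0 and "$BEGINDATA" in text:
        data_start, data_end = int(text["$BEGINDATA"]), int(text["$ENDDATA"])

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "I").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    if text.get("$MODE", "L").upper() != "L":
        raise FormatError(f"only list mode supported, got $MODE={text.get('$MODE')!r}")

    bits = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]
    if datatype == "I":
        dmap = {8: "u1", 16: "u2", 32: "u4"}
    elif datatype == "F":
        dmap = {32: "f4"}
    elif datatype == "D":
        dmap = {64: "f8"}
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")
    try:
        dtypes = [("<" if little else ">") + dmap[b] for b in bits]
    except KeyError as e:
        raise FormatError(f"unsupported {datatype}-type bit width {e}") from None
    if len(set(dtypes)) != 1:
        raise FormatError("mixed per-parameter bit widths are not supported")
    data = np.frombuffer(
        raw, dtype=dtypes[0], count=n_par * n_tot, offset=data_start
    ).reshape(n_tot, n_par)

    aliases = param_aliases or DEFAULT_PARAM_ALIASES
    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", text.get(f"$P{i}S", f"P{i}")))
    cols: dict[str, np.ndarray] = {}
    for target, wanted in aliases.items():
        wanted_up = tuple(w.upper() for w in wanted)
        for j, name in enumerate(names):
            if name.upper() in wanted_up:
                cols[target] = data[:, j]
                break
        else:
            raise FormatError(
                f"cannot map parameter {target!r}: file has {names}, "
                f"accepted aliases {list(wanted)}"
            )
    for k, v in cols.items():
        if v.min() < 0 or v.max() > CHANNEL_MAX:
            raise FormatError(f"{k}: channel values outside [0, {CHANNEL_MAX}]")
    return EventTable(
        fsc=np.asarray(np.round(cols["fsc"]), dtype=np.int64),
        ssc=np.asarray(np.round(cols["ssc"]), dtype=np.int64),
        fl1=np.asarray(np.round(cols["fl1"]), dtype=np.int64),
        sample_id=sample_id or Path(path).stem,
        role=role,
    )


def write_fcs(events: EventTable, path: PathLike) -> None:
    """Write an FCS 3.0 list-mode file (16-bit integers, little-endian).

    Used to generate round-trip fixtures and to export simulated events in
    the instrument's native container.
    """
    names = ("FSC", "SSC", "FL1")
    data = np.column_stack([events.fsc, events.ssc, events.fl1]).astype("<u2")
    payload = data.tobytes()
    n_tot, n_par = data.shape

    header_len = 58
    # build TEXT with placeholder offsets, then patch (lengths kept fixed)
    def make_text(begin: int, end: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": f"{begin:010d}", "$ENDDATA": f"{end:010d}",
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "I", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
        }
        for i, name in enumerate(names, start=1):
            kv[f"$P{i}N"] = name
            kv[f"$P{i}B"] = "16"
            kv[f"$P{i}R"] = "4096"
            kv[f"$P{i}E"] = "0,0"
        body = "/" + "".join(f"{k}/{v}/" for k, v in kv.items())
        return body.encode("ascii")

    text = make_text(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    text = make_text(data_start, data_end)
    assert text_start + len(text) - 1 == text_end

    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode() + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode() + f"{data_end:8d}".encode()
        + f"{0:8d}".encode() + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + payload)


def read_events(path: PathLike, sample_id: str = "", role: str = "sample") -> EventTable:
    """Dispatch on file content: FCS magic bytes, else CSV."""
    p = Path(path)
    with open(p, "rb") as fh:
        magic = fh.read(3)
    if magic == b"FCS":
        return read_fcs(p, sample_id=sample_id, role=role)
    return read_events_csv(p, sample_id=sample_id, role=role)


# ---------------------------------------------------------------------------
# JSON result emission

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=True))
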