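"""File I/O: vitals/trace/events CSV dialects and calibration configs.

Vitals CSV columns: ``time_s, etco2_mmhg, rr_bpm, spo2_pct, pr_bpm``.
On read, rows are validated per channel (unparseable or non-finite
values are flagged invalid, out-of-range values clamped and flagged)
and resampled onto a 1 Hz grid by nearest neighbor with a <= 1 s
tolerance; grid seconds without a close enough source sample become
invalid (trace gaps), never exceptions. Calibration configs round-trip
through YAML or JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import (
    AgeMode,
    CHANNELS,
    CalibrationConfig,
    IPITrace,
    VitalStream,
    default_config,
)
from .errors import VitalsFormatError
from .events import ClinicalEvent, IPIEvent

__all__ = [
    "VITALS_COLUMNS",
    "read_vitals_csv",
    "write_vitals_csv",
    "write_trace_csv",
    "write_events_csv",
    "load_config",
    "dump_config",
]

logger = logging.getLogger("ipindex")

CHANNEL_COLUMNS = {
    "etco2": "etco2_mmhg",
    "rr": "rr_bpm",
    "spo2": "spo2_pct",
    "pr": "pr_bpm",
}
VITALS_COLUMNS = ("time_s",) + tuple(CHANNEL_COLUMNS[ch] for ch in CHANNELS)

RESAMPLE_TOLERANCE_S = 1.0


def _nearest_indices(t_src: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Index of the nearest source time per grid second (ties to the
    earlier sample); -1 where no source time is within tolerance."""
    pos = np.searchsorted(t_src, t_grid)
    left = np.clip(pos - 1, 0, len(t_src) - 1)
    right = np.clip(pos, 0, len(t_src) - 1)
    d_left = np.abs(t_grid - t_src[left])
    d_right = np.abs(t_src[right] - t_grid)
    idx = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    return np.where(dist <= RESAMPLE_TOLERANCE_S, idx, -1)


def read_vitals_csv(
    path: str | Path,
    mode: AgeMode | str = AgeMode.ADULT,
    config: CalibrationConfig | None = None,
) -> VitalStream:
    """Parse, validate, clamp and resample a vitals CSV to 1 Hz."""
    path = Path(path)
    cfg = config if config is not None else default_config(mode)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise VitalsFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")
    cols = {c: pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
            for c in VITALS_COLUMNS}
    n_bad = sum(int(np.isnan(v).sum()) for c, v in cols.items())
    if n_bad:
        logger.warning("%s: %d unparseable value(s) marked invalid",
                       path.name, n_bad)
    t_src = cols["time_s"]
    keep = np.isfinite(t_src)
    order = np.argsort(t_src[keep], kind="stable")
    t_src = t_src[keep][order]
    if t_src.size == 0:
        raise VitalsFormatError(f"{path.name}: no parseable time_s values")

    t0 = t_src[0]
    n = int(np.floor(t_src[-1] - t0)) + 1
    t_grid = t0 + np.arange(n, dtype=float)
    idx = _nearest_indices(t_src, t_grid)
    have = idx >= 0

    data, valid, clamped = {}, [], []
    for ch in CHANNELS:
        raw = cols[CHANNEL_COLUMNS[ch]][keep][order]
        x = np.full(n, np.nan)
        x[have] = raw[idx[have]]
        lo, hi = cfg.partition(ch).domain
        ok = np.isfinite(x)
        cl = ok & ((x < lo) | (x > hi))
        if cl.any():
            logger.warning("%s: %d %s value(s) clamped to [%g, %g]",
                           path.name, int(cl.sum()), ch, lo, hi)
        data[ch] = np.where(ok, np.clip(x, lo, hi), np.nan)
        valid.append(ok)
        clamped.append(cl)
    return VitalStream(
        t=t_grid - t0, mode=cfg.mode if config is not None else mode,
        valid=np.column_stack(valid), clamped=np.column_stack(clamped),
        **data)


def write_vitals_csv(stream: VitalStream, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": stream.t})
    for ch in CHANNELS:
        df[CHANNEL_COLUMNS[ch]] = stream.channel(ch)
    df.to_csv(path, index=False)


def write_trace_csv(trace: IPITrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_events_csv(
    events: Iterable[ClinicalEvent | IPIEvent],
    path: str | Path,
) -> None:
    rows = []
    for ev in events:
        kind = getattr(ev, "kind", None)
        if kind is None:
            kind = f"ipi_le_{ev.threshold}"
        rows.append({"kind": kind, "start_s": ev.start_s, "end_s": ev.end_s,
                     "duration_s": ev.end_s - ev.start_s})
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "duration_s"]) \
        .to_csv(path, index=False)


def load_config(path: str | Path) -> CalibrationConfig:
    """Load a calibration config from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    return CalibrationConfig.from_dict(data)


def dump_config(config: CalibrationConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
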