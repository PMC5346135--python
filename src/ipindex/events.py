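"""Respiratory-compromise event detection on 1 Hz vital-sign streams.

Two prospectively defined event classes are detected as maximal runs of
per-second threshold conditions:

severe events
    * apnea -- PetCO2 = 0 mmHg and RR = 0 bpm for >= 30 s
    * hypoxia -- SpO2 <= 85 % for >= 15 s

clinically significant events
    * central/obstructive apnea -- PetCO2 = 0, RR = 0 for >= 15 s
    * bradypneic hypoventilation with hypoxia -- PetCO2 > 50, RR < 8,
      SpO2 < 90 % for >= 15 s
    * non-bradypneic hypoventilation with hypoxia -- PetCO2 < 30,
      RR 8-12, SpO2 < 90 % for >= 15 s
    * hypoxia -- SpO2 < 90 % (any PetCO2/RR) for >= 15 s

"= 0" is tested as "< 1" (sensor-quantization guard against CSV float
round-trips); all other comparisons are exactly as printed. Runs are
maximal with no merge gap -- a single interrupted second splits an
event -- and invalid samples break condition runs. One physiological
episode may legitimately yield events of several kinds (a 40-s apnea is
both a severe and a clinically significant apnea); the epoch-based
analysis counts overlap harmlessly.

IPI events are runs of rounded IPI <= threshold (1-9) lasting >= 15 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .engine import CHANNELS, IPITrace, VitalStream

__all__ = [
    "ClinicalEvent",
    "IPIEvent",
    "EVENT_KINDS",
    "SEVERE_KINDS",
    "CLINICALLY_SIGNIFICANT_KINDS",
    "kinds_for_class",
    "detect_events",
    "detect_ipi_events",
    "IPI_EVENT_MIN_S",
]

IPI_EVENT_MIN_S = 15


@dataclass(frozen=True, order=True)
class ClinicalEvent:
    """Labeled [start_s, end_s) interval on the 1 Hz grid."""

    start_s: int
    end_s: int
    kind: str

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True, order=True)
class IPIEvent:
    """Maximal run of IPI <= ``threshold`` lasting >= 15 s."""

    start_s: int
    end_s: int
    threshold: int

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


def _apnea(s: VitalStream) -> np.ndarray:
    return (s.etco2 < 1.0) & (s.rr < 1.0)


def _severe_hypoxia(s: VitalStream) -> np.ndarray:
    return s.spo2 <= 85.0


def _brady_hypovent(s: VitalStream) -> np.ndarray:
    return (s.etco2 > 50.0) & (s.rr < 8.0) & (s.spo2 < 90.0)


def _nonbrady_hypovent(s: VitalStream) -> np.ndarray:
    return (s.etco2 < 30.0) & (s.rr >= 8.0) & (s.rr <= 12.0) & (s.spo2 < 90.0)


def _hypoxia(s: VitalStream) -> np.ndarray:
    return s.spo2 < 90.0


# kind -> (minimum duration s, channels whose validity the condition needs,
#          per-second predicate)
EVENT_DEFINITIONS: dict[str, tuple[int, tuple[str, ...], Callable]] = {
    "severe_apnea": (30, ("etco2", "rr"), _apnea),
    "severe_hypoxia": (15, ("spo2",), _severe_hypoxia),
    "cs_apnea": (15, ("etco2", "rr"), _apnea),
    "cs_bradypneic_hypovent_hypoxia": (15, ("etco2", "rr", "spo2"), _brady_hypovent),
    "cs_nonbradypneic_hypovent_hypoxia": (15, ("etco2", "rr", "spo2"),
                                          _nonbrady_hypovent),
    "cs_hypoxia": (15, ("spo2",), _hypoxia),
}

EVENT_KINDS = tuple(EVENT_DEFINITIONS)
SEVERE_KINDS = ("severe_apnea", "severe_hypoxia")
CLINICALLY_SIGNIFICANT_KINDS = tuple(k for k in EVENT_KINDS if k.startswith("cs_"))


def kinds_for_class(event_class: str) -> tuple[str, ...]:
    if event_class == "severe":
        return SEVERE_KINDS
    if event_class == "clinically_significant":
        return CLINICALLY_SIGNIFICANT_KINDS
    raise ValueError(
        f"event_class must be 'severe' or 'clinically_significant', "
        f"got {event_class!r}")


def _maximal_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) bounds of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False]))))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def _channel_valid(stream: VitalStream, channels: Sequence[str]) -> np.ndarray:
    idx = [CHANNELS.index(ch) for ch in channels]
    return stream.valid[:, idx].all(axis=1)


def detect_events(
    stream: VitalStream,
    kinds: Iterable[str] | None = None,
) -> list[ClinicalEvent]:
    """Detect all (or the requested) event kinds on a 1 Hz stream."""
    out: list[ClinicalEvent] = []
    for kind in (EVENT_KINDS if kinds is None else tuple(kinds)):
        try:
            min_s, channels, predicate = EVENT_DEFINITIONS[kind]
        except KeyError:
            raise ValueError(f"unknown event kind {kind!r}") from None
        cond = predicate(stream) & _channel_valid(stream, channels)
        for start, end in _maximal_runs(cond):
            if end - start >= min_s:
                out.append(ClinicalEvent(start_s=start, end_s=end, kind=kind))
    return sorted(out)


def detect_ipi_events(trace: IPITrace, threshold: int) -> list[IPIEvent]:
    """Maximal runs of rounded IPI <= ``threshold`` lasting >= 15 s.

    Trace gaps (invalid seconds) break runs. ``threshold`` must lie in
    1..9 -- IPI 10 is the optimal state, not an event threshold.
    """
    threshold = int(threshold)
    if not 1 <= threshold <= 9:
        raise ValueError(f"IPI event threshold must be in 1..9, got {threshold}")
    with np.errstate(invalid="ignore"):
        mask = trace.valid & (trace.ipi <= threshold)
    return [
        IPIEvent(start_s=start, end_s=end, threshold=threshold)
        for start, end in _maximal_runs(mask)
        if end - start >= IPI_EVENT_MIN_S
    ]
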