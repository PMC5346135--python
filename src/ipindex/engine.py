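"""The Integrated Pulmonary Index (IPI) model.

The IPI fuses four continuously monitored vital signs -- end-tidal CO2
(PetCO2, mmHg), respiration rate (RR, breaths/min), oxygen saturation
(SpO2, %) and pulse rate (PR, beats/min) -- into a single score between
1 (critical respiratory insufficiency, immediate intervention required)
and 10 (optimal respiratory status).

PetCO2 and RR are described by five fuzzy sets (VL, L, N, H, VH), SpO2
and PR by three (L, N, H). The primary rule base is a complete
RR x PetCO2 matrix of consequents per SpO2 label; a normal SpO2
reproduces the base matrix, a low SpO2 replaces it with a uniformly
lower one (desaturation always pulls the score down). PR acts only as a
secondary parameter: when a low pulse accompanies high PetCO2 and RR, or
a high pulse accompanies low PetCO2 and RR, one point is subtracted from
the defuzzified score, graded by the fuzzy degree of the compound
condition so the output stays continuous.

Adult and three pediatric modes (1-3, 3-6, 6-12 years) differ only in
the RR and PR partitions; PetCO2 and SpO2 partitions and the rule
matrices are shared. The index is intentionally non-adaptive: no
temporal smoothing, trend tracking or per-patient baseline is applied.

Exact set breakpoints and matrix cells were never published; the shipped
defaults are a calibration that reproduces the published worked example
(RR 12, PetCO2 26 under normal SpO2/PR scores 8; SpO2 90 drops it to 5),
pins all-normal vitals to 10 and apneic/hypoxic extremes to 1, and keeps
the score monotone under single-parameter deterioration.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fuzzy
from .errors import ConfigurationError
from .fuzzy import FuzzyPartition, FuzzyRule, TrapezoidMF, TriangularConsequents

__all__ = [
    "CHANNELS",
    "AgeMode",
    "VitalSample",
    "VitalStream",
    "IPIResult",
    "IPITrace",
    "PRRule",
    "RuleBase",
    "CalibrationConfig",
    "default_partitions",
    "default_rulebase",
    "default_config",
    "compute_ipi",
    "apply_pr_adjustment",
    "compute_ipi_batch",
    "compute_ipi_stream",
    "grid_extrema",
    "score",
]

CHANNELS = ("etco2", "rr", "spo2", "pr")
FIVE_LABELS = ("VL", "L", "N", "H", "VH")
THREE_LABELS = ("L", "N", "H")


class AgeMode(str, enum.Enum):
    """Patient age mode; below 1 year the index is undefined."""

    ADULT = "adult"
    PED_1_3 = "ped_1_3"
    PED_3_6 = "ped_3_6"
    PED_6_12 = "ped_6_12"

    @classmethod
    def coerce(cls, value) -> "AgeMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ConfigurationError(
                f"unknown age mode {value!r}; expected one of "
                f"{[m.value for m in cls]}") from None


def _partition(name: str, labels: Sequence[str], quads) -> FuzzyPartition:
    return FuzzyPartition(
        name=name,
        functions=tuple((lab, TrapezoidMF(*q)) for lab, q in zip(labels, quads)),
    )


# PetCO2 and SpO2 partitions are shared by all age modes.
_ETCO2_QUADS = ((0, 0, 12, 20), (12, 20, 30, 35), (30, 35, 45, 50),
                (45, 50, 60, 70), (60, 70, 150, 150))
_SPO2_QUADS = ((0, 0, 85, 94), (85, 94, 99.5, 100), (99.5, 100, 100, 100))

# RR / PR plateaus per age mode, from standard adult and pediatric
# vital-sign reference ranges (toddler 24-40 bpm / 90-150 bpm etc.).
_RR_QUADS = {
    AgeMode.ADULT: ((0, 0, 4, 6), (4, 6, 9, 11), (9, 11, 20, 25),
                    (20, 25, 30, 35), (30, 35, 60, 60)),
    AgeMode.PED_1_3: ((0, 0, 6, 10), (6, 10, 18, 22), (18, 22, 34, 40),
                      (34, 40, 50, 58), (50, 58, 90, 90)),
    AgeMode.PED_3_6: ((0, 0, 5, 9), (5, 9, 16, 20), (16, 20, 32, 38),
                      (32, 38, 48, 56), (48, 56, 90, 90)),
    AgeMode.PED_6_12: ((0, 0, 5, 8), (5, 8, 14, 17), (14, 17, 28, 34),
                       (28, 34, 44, 52), (44, 52, 90, 90)),
}
_PR_QUADS = {
    AgeMode.ADULT: ((0, 0, 45, 55), (45, 55, 100, 120), (100, 120, 250, 250)),
    AgeMode.PED_1_3: ((0, 0, 70, 90), (70, 90, 150, 170), (150, 170, 250, 250)),
    AgeMode.PED_3_6: ((0, 0, 60, 80), (60, 80, 140, 160), (140, 160, 250, 250)),
    AgeMode.PED_6_12: ((0, 0, 55, 70), (55, 70, 120, 140), (120, 140, 250, 250)),
}

# Consequent matrices, rows = RR label (VL..VH), cols = PetCO2 label
# (VL..VH). The normal-SpO2 layer is the base RR x PetCO2 matrix; the
# high-SpO2 layer is identical (a high saturation is not a deficit); the
# low-SpO2 layer is uniformly <= the base layer.
_BASE_MATRIX = (
    (1, 2, 3, 2, 1),
    (3, 5, 6, 5, 3),
    (6, 8, 10, 8, 6),
    (4, 6, 8, 6, 4),
    (2, 3, 5, 3, 2),
)
_LOW_SPO2_MATRIX = (
    (1, 1, 1, 1, 1),
    (1, 2, 3, 2, 1),
    (2, 2, 3, 2, 2),
    (1, 2, 3, 2, 1),
    (1, 1, 2, 1, 1),
)


@dataclass(frozen=True)
class PRRule:
    """Secondary pulse-rate rule: subtract ``subtract`` IPI points, graded
    by min(PR-label grade, max PetCO2-label grade, max RR-label grade)."""

    pr_label: str
    etco2_labels: tuple[str, ...]
    rr_labels: tuple[str, ...]
    subtract: float = 1.0


DEFAULT_PR_RULES = (
    PRRule("L", ("H", "VH"), ("H", "VH")),
    PRRule("H", ("L", "VL"), ("L", "VL")),
)


@dataclass(frozen=True)
class RuleBase:
    """Complete antecedent coverage: one consequent per
    (RR label x PetCO2 label x SpO2 label) cell, plus PR rules."""

    matrices: tuple[tuple[str, tuple[tuple[int, ...], ...]], ...]
    pr_rules: tuple[PRRule, ...] = DEFAULT_PR_RULES

    def __post_init__(self) -> None:
        mats = dict(self.matrices)
        if set(mats) != set(THREE_LABELS):
            raise ConfigurationError(
                f"rule base must define one matrix per SpO2 label {THREE_LABELS}, "
                f"got {sorted(mats)}")
        for lab, m in mats.items():
            if len(m) != len(FIVE_LABELS) or any(len(r) != len(FIVE_LABELS) for r in m):
                raise ConfigurationError(
                    f"SpO2={lab} matrix must be 5x5 (RR x PetCO2)")
            for row in m:
                for v in row:
                    if not 1 <= int(v) <= 10:
                        raise ConfigurationError(
                            f"consequent {v} outside 1..10 in SpO2={lab} matrix")
        # Desaturation must never raise the score.
        for i in range(5):
            for j in range(5):
                if not (mats["L"][i][j] <= mats["N"][i][j] <= mats["H"][i][j]):
                    raise ConfigurationError(
                        "decreasing SpO2 label must not increase the consequent "
                        f"(cell RR={FIVE_LABELS[i]}, PetCO2={FIVE_LABELS[j]})")
        for r in self.pr_rules:
            if r.pr_label not in THREE_LABELS:
                raise ConfigurationError(f"unknown PR label {r.pr_label!r}")
            for lab in r.etco2_labels + r.rr_labels:
                if lab not in FIVE_LABELS:
                    raise ConfigurationError(f"unknown label {lab!r} in PR rule")

    def matrix(self, spo2_label: str) -> tuple[tuple[int, ...], ...]:
        return dict(self.matrices)[spo2_label]

    def consequent(self, rr_label: str, etco2_label: str, spo2_label: str) -> int:
        m = self.matrix(spo2_label)
        return m[FIVE_LABELS.index(rr_label)][FIVE_LABELS.index(etco2_label)]

    def rules(self) -> list[FuzzyRule]:
        """The 75 primary rules as explicit :class:`FuzzyRule` objects."""
        out = []
        for s_lab in THREE_LABELS:
            m = self.matrix(s_lab)
            for i, r_lab in enumerate(FIVE_LABELS):
                for j, c_lab in enumerate(FIVE_LABELS):
                    out.append(FuzzyRule(
                        {"rr": r_lab, "etco2": c_lab, "spo2": s_lab}, m[i][j]))
        return out


def default_rulebase() -> RuleBase:
    """The shipped calibrated rule base (see module docstring)."""
    return RuleBase(matrices=(
        ("L", _LOW_SPO2_MATRIX),
        ("N", _BASE_MATRIX),
        ("H", _BASE_MATRIX),
    ))


def default_partitions(mode: AgeMode | str = AgeMode.ADULT) -> dict[str, FuzzyPartition]:
    """Calibrated membership partitions for ``mode``.

    PetCO2/SpO2 partitions are identical in all modes; RR/PR plateaus
    shift with the pediatric age range.
    """
    mode = AgeMode.coerce(mode)
    return {
        "etco2": _partition("etco2", FIVE_LABELS, _ETCO2_QUADS),
        "rr": _partition("rr", FIVE_LABELS, _RR_QUADS[mode]),
        "spo2": _partition("spo2", THREE_LABELS, _SPO2_QUADS),
        "pr": _partition("pr", THREE_LABELS, _PR_QUADS[mode]),
    }


@dataclass(frozen=True)
class CalibrationConfig:
    """Immutable bundle of partitions + rule base for one age mode."""

    mode: AgeMode
    partitions: tuple[tuple[str, FuzzyPartition], ...]
    rulebase: RuleBase
    consequents: TriangularConsequents = field(default_factory=TriangularConsequents)

    def __post_init__(self) -> None:
        parts = dict(self.partitions)
        if set(parts) != set(CHANNELS):
            raise ConfigurationError(
                f"partitions must cover channels {CHANNELS}, got {sorted(parts)}")
        for ch, labels in (("etco2", FIVE_LABELS), ("rr", FIVE_LABELS),
                           ("spo2", THREE_LABELS), ("pr", THREE_LABELS)):
            if parts[ch].labels != labels:
                raise ConfigurationError(
                    f"partition {ch} must use labels {labels}, got {parts[ch].labels}")

    def partition(self, channel: str) -> FuzzyPartition:
        return dict(self.partitions)[channel]

    def to_dict(self) -> dict:
        parts = dict(self.partitions)
        return {
            "mode": self.mode.value,
            "partitions": {
                ch: {lab: [mf.a, mf.b, mf.c, mf.d]
                     for lab, mf in parts[ch].functions}
                for ch in CHANNELS
            },
            "rules": {f"spo2_{lab}": [list(r) for r in m]
                      for lab, m in self.rulebase.matrices},
            "pr_rules": [
                {"pr": r.pr_label, "etco2": list(r.etco2_labels),
                 "rr": list(r.rr_labels), "subtract": r.subtract}
                for r in self.rulebase.pr_rules
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CalibrationConfig":
        try:
            mode = AgeMode.coerce(data.get("mode", "adult"))
            # label order is canonical, not file order (YAML/JSON may sort keys)
            label_order = {"etco2": FIVE_LABELS, "rr": FIVE_LABELS,
                           "spo2": THREE_LABELS, "pr": THREE_LABELS}
            partitions = tuple(
                (ch, _partition(
                    ch, label_order[ch],
                    tuple(tuple(data["partitions"][ch][lab])
                          for lab in label_order[ch])))
                for ch in CHANNELS
            )
            matrices = tuple(
                (lab, tuple(tuple(int(v) for v in row)
                            for row in data["rules"][f"spo2_{lab}"]))
                for lab in THREE_LABELS
            )
            pr_rules = tuple(
                PRRule(r["pr"], tuple(r["etco2"]), tuple(r["rr"]),
                       float(r.get("subtract", 1.0)))
                for r in data.get("pr_rules", [])
            ) or DEFAULT_PR_RULES
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed calibration config: {exc}") from exc
        return cls(mode=mode, partitions=partitions,
                   rulebase=RuleBase(matrices=matrices, pr_rules=pr_rules))

    def checksum(self) -> str:
        """SHA-256 over the canonical JSON form (logged for reproducibility)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@lru_cache(maxsize=None)
def _default_config_cached(mode: AgeMode) -> CalibrationConfig:
    return CalibrationConfig(
        mode=mode,
        partitions=tuple(default_partitions(mode).items()),
        rulebase=default_rulebase(),
    )


def default_config(mode: AgeMode | str = AgeMode.ADULT) -> CalibrationConfig:
    """Shipped calibration for ``mode`` (cached, immutable)."""
    return _default_config_cached(AgeMode.coerce(mode))


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class VitalSample:
    """One synchronized four-channel observation at time ``t`` (seconds)."""

    t: float
    etco2: float
    rr: float
    spo2: float
    pr: float
    valid: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def channel(self, name: str) -> float:
        return getattr(self, name)

    def all_valid(self) -> bool:
        return all(self.valid) and all(
            np.isfinite(self.channel(ch)) for ch in CHANNELS)


@dataclass
class VitalStream:
    """Uniform 1 Hz four-channel recording.

    ``valid``/``clamped`` are (n, 4) boolean arrays in channel order
    ``CHANNELS``; an invalid channel second produces a gap in the IPI
    trace rather than an exception.
    """

    t: np.ndarray
    etco2: np.ndarray
    rr: np.ndarray
    spo2: np.ndarray
    pr: np.ndarray
    valid: np.ndarray | None = None
    clamped: np.ndarray | None = None
    mode: AgeMode = AgeMode.ADULT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for ch in CHANNELS:
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        n = len(self.t)
        for ch in CHANNELS:
            if len(getattr(self, ch)) != n:
                raise ValueError(f"channel {ch} length mismatch")
        if self.valid is None:
            self.valid = np.ones((n, len(CHANNELS)), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).reshape(n, len(CHANNELS))
        self.valid = self.valid & np.column_stack(
            [np.isfinite(getattr(self, ch)) for ch in CHANNELS])
        if self.clamped is None:
            self.clamped = np.zeros((n, len(CHANNELS)), dtype=bool)
        else:
            self.clamped = np.asarray(self.clamped, dtype=bool).reshape(n, len(CHANNELS))
        if n > 1 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("VitalStream requires a uniform 1 Hz time grid")
        self.mode = AgeMode.coerce(self.mode)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(len(self))

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def sample(self, i: int) -> VitalSample:
        return VitalSample(
            t=float(self.t[i]),
            etco2=float(self.etco2[i]), rr=float(self.rr[i]),
            spo2=float(self.spo2[i]), pr=float(self.pr[i]),
            valid=tuple(bool(v) for v in self.valid[i]),
        )

    def slice(self, start: int, stop: int) -> "VitalStream":
        return VitalStream(
            t=self.t[start:stop], etco2=self.etco2[start:stop],
            rr=self.rr[start:stop], spo2=self.spo2[start:stop],
            pr=self.pr[start:stop], valid=self.valid[start:stop],
            clamped=self.clamped[start:stop], mode=self.mode,
        )

    @classmethod
    def concat(cls, streams: Sequence["VitalStream"]) -> "VitalStream":
        if not streams:
            raise ValueError("cannot concatenate zero streams")
        mode = streams[0].mode
        if any(s.mode != mode for s in streams):
            raise ValueError("cannot concatenate streams with different modes")
        n = sum(len(s) for s in streams)
        return cls(
            t=np.arange(n, dtype=float),
            etco2=np.concatenate([s.etco2 for s in streams]),
            rr=np.concatenate([s.rr for s in streams]),
            spo2=np.concatenate([s.spo2 for s in streams]),
            pr=np.concatenate([s.pr for s in streams]),
            valid=np.concatenate([s.valid for s in streams]),
            clamped=np.concatenate([s.clamped for s in streams]),
            mode=mode,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.t, "etco2_mmhg": self.etco2, "rr_bpm": self.rr,
            "spo2_pct": self.spo2, "pr_bpm": self.pr,
        })
        df["valid"] = self.valid.all(axis=1).astype(int)
        return df


@dataclass
class IPIResult:
    """Scored single sample; ``ipi`` is None when any channel is invalid."""

    t: float
    ipi: int | None
    ipi_raw: float
    pr_adjustment: float
    pr_adjustment_applied: bool
    grades: dict[str, dict[str, float]] | None
    valid: bool
    reason: str | None = None


@dataclass
class IPITrace:
    """Per-second IPI results; invalid seconds carry NaN (trace gaps)."""

    t: np.ndarray
    ipi_raw: np.ndarray
    ipi: np.ndarray
    pr_adjustment: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def ipi_int(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(
            np.where(self.valid, self.ipi, 0).astype(int), mask=~self.valid)

    def slice(self, start: int, stop: int) -> "IPITrace":
        return IPITrace(self.t[start:stop], self.ipi_raw[start:stop],
                        self.ipi[start:stop], self.pr_adjustment[start:stop],
                        self.valid[start:stop])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t,
            "ipi": self.ipi,
            "ipi_raw": self.ipi_raw,
            "pr_adjustment": self.pr_adjustment,
            "flags": np.where(self.valid, "ok", "invalid"),
        })


# ---------------------------------------------------------------------------
# Scoring


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _pr_adjustment_amount(grades: Mapping[str, Mapping[str, float]],
                          pr_rules: Sequence[PRRule]) -> float:
    amount = 0.0
    for rule in pr_rules:
        cond = min(
            grades["pr"][rule.pr_label],
            max(grades["etco2"][lab] for lab in rule.etco2_labels),
            max(grades["rr"][lab] for lab in rule.rr_labels),
        )
        amount = max(amount, cond * rule.subtract)
    return amount


def apply_pr_adjustment(
    ipi_raw: float,
    grades: Mapping[str, Mapping[str, float]],
    pr_rules: Sequence[PRRule] = DEFAULT_PR_RULES,
) -> float:
    """Graded secondary pulse-rate subtraction, floored at 1.

    At fully crisp condition grades this reduces exactly to "subtract
    one from the calculated IPI value"; in between, the subtraction is
    the fuzzy degree of the compound condition, keeping the score
    continuous in its inputs.
    """
    return max(1.0, float(ipi_raw) - _pr_adjustment_amount(grades, pr_rules))


def compute_ipi(
    sample: VitalSample,
    mode: AgeMode | str | None = None,
    config: CalibrationConfig | None = None,
) -> IPIResult:
    """Score a single sample: fuzzify -> rules -> centroid -> PR adjust
    -> round (half-up) and clamp to [1, 10].

    Any invalid channel yields a no-score result carrying the reason
    (a gap in the trace), never an exception.
    """
    cfg = config if config is not None else default_config(mode or AgeMode.ADULT)
    bad = [ch for ch, ok in zip(CHANNELS, sample.valid) if not ok]
    bad += [ch for ch in CHANNELS
            if ch not in bad and not np.isfinite(sample.channel(ch))]
    if bad:
        return IPIResult(t=sample.t, ipi=None, ipi_raw=float("nan"),
                         pr_adjustment=float("nan"), pr_adjustment_applied=False,
                         grades=None, valid=False,
                         reason=f"invalid channel(s): {', '.join(bad)}")
    grades = {ch: cfg.partition(ch).fuzzify(sample.channel(ch)) for ch in CHANNELS}
    acts = fuzzy.evaluate_rules(grades, cfg.rulebase.rules())
    raw = fuzzy.defuzzify_centroid(acts, cfg.consequents)
    amount = _pr_adjustment_amount(grades, cfg.rulebase.pr_rules)
    adjusted = max(1.0, raw - amount)
    ipi = int(np.clip(_round_half_up(adjusted), 1, 10))
    return IPIResult(t=sample.t, ipi=ipi, ipi_raw=raw, pr_adjustment=amount,
                     pr_adjustment_applied=amount > 0.0, grades=grades, valid=True)


def score(etco2: float, rr: float, spo2: float, pr: float,
          mode: AgeMode | str = AgeMode.ADULT,
          config: CalibrationConfig | None = None) -> int:
    """Convenience wrapper: rounded IPI for one set of crisp values."""
    res = compute_ipi(VitalSample(t=0.0, etco2=etco2, rr=rr, spo2=spo2, pr=pr),
                      mode=mode, config=config)
    assert res.ipi is not None
    return res.ipi


def _grade_arrays(cfg: CalibrationConfig, arrays: Mapping[str, np.ndarray]):
    return {ch: cfg.partition(ch).fuzzify_array(arrays[ch]) for ch in arrays}


def _activation_arrays(cfg: CalibrationConfig, g_rr, g_etco2, g_spo2):
    """Per-level activation arrays via the matrix layout (vectorized
    equivalent of evaluate_rules over the 75 primary rules)."""
    act: dict[int, np.ndarray] = {}
    for s_lab in THREE_LABELS:
        m = cfg.rulebase.matrix(s_lab)
        gs = g_spo2[s_lab]
        for i, r_lab in enumerate(FIVE_LABELS):
            for j, c_lab in enumerate(FIVE_LABELS):
                a = np.minimum(np.minimum(g_rr[r_lab], g_etco2[c_lab]), gs)
                k = m[i][j]
                act[k] = a if k not in act else np.maximum(act[k], a)
    return act


def _centroid_arrays(cfg: CalibrationConfig, act: Mapping[int, np.ndarray]):
    num = 0.0
    den = 0.0
    for k in sorted(act):
        w = cfg.consequents.clipped_area(act[k])
        num = num + k * w
        den = den + w
    return num / den


def _pr_amount_arrays(cfg: CalibrationConfig, g_etco2, g_rr, g_pr):
    amount = 0.0
    for rule in cfg.rulebase.pr_rules:
        c_cond = g_etco2[rule.etco2_labels[0]]
        for lab in rule.etco2_labels[1:]:
            c_cond = np.maximum(c_cond, g_etco2[lab])
        r_cond = g_rr[rule.rr_labels[0]]
        for lab in rule.rr_labels[1:]:
            r_cond = np.maximum(r_cond, g_rr[lab])
        cond = np.minimum(np.minimum(g_pr[rule.pr_label], c_cond), r_cond)
        amount = np.maximum(amount, cond * rule.subtract)
    return amount


def compute_ipi_batch(
    etco2, rr, spo2, pr,
    mode: AgeMode | str | None = None,
    config: CalibrationConfig | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized scoring over broadcastable arrays of crisp inputs.

    Returns ``{"ipi_raw", "pr_adjustment", "ipi"}``; identical sample by
    sample to :func:`compute_ipi` (the scalar path goes through the
    generic rule evaluator, this one through the matrix layout).
    """
    cfg = config if config is not None else default_config(mode or AgeMode.ADULT)
    etco2, rr, spo2, pr = np.broadcast_arrays(
        np.asarray(etco2, float), np.asarray(rr, float),
        np.asarray(spo2, float), np.asarray(pr, float))
    g = _grade_arrays(cfg, {"etco2": etco2, "rr": rr, "spo2": spo2, "pr": pr})
    act = _activation_arrays(cfg, g["rr"], g["etco2"], g["spo2"])
    raw = _centroid_arrays(cfg, act)
    amount = np.broadcast_to(
        _pr_amount_arrays(cfg, g["etco2"], g["rr"], g["pr"]), raw.shape)
    adjusted = np.maximum(1.0, raw - amount)
    ipi = np.clip(_round_half_up(adjusted), 1, 10).astype(int)
    return {"ipi_raw": raw, "pr_adjustment": np.asarray(amount, float), "ipi": ipi}


def compute_ipi_stream(
    stream: VitalStream,
    config: CalibrationConfig | None = None,
) -> IPITrace:
    """One IPI per 1 Hz grid second; invalid-channel seconds yield gaps.

    The computation is stateless in time (no smoothing), so the trace is
    invariant under splitting the stream and concatenating the results.
    """
    cfg = config if config is not None else default_config(stream.mode)
    n = len(stream)
    raw = np.full(n, np.nan)
    ipi = np.full(n, np.nan)
    amount = np.full(n, np.nan)
    ok = stream.valid.all(axis=1)
    if ok.any():
        res = compute_ipi_batch(
            stream.etco2[ok], stream.rr[ok], stream.spo2[ok], stream.pr[ok],
            config=cfg)
        raw[ok] = res["ipi_raw"]
        ipi[ok] = res["ipi"]
        amount[ok] = res["pr_adjustment"]
    return IPITrace(t=stream.t.copy(), ipi_raw=raw, ipi=ipi,
                    pr_adjustment=amount, valid=ok)


def grid_extrema(
    mode: AgeMode | str = AgeMode.ADULT,
    config: CalibrationConfig | None = None,
    etco2: np.ndarray | None = None,
    rr: np.ndarray | None = None,
    spo2: np.ndarray | None = None,
    pr: np.ndarray | None = None,
) -> tuple[int, int, int]:
    """(min, max, n_points) of the rounded IPI over a dense input grid.

    Exhaustive search over the Cartesian product of the four axes,
    decomposed to stay in memory: the defuzzified score depends only on
    (etco2, rr, spo2) and the PR subtraction only on (etco2, rr, pr), so
    the two are combined chunk-wise. Defaults reproduce the physical
    domain at step 1: etco2 0-100 mmHg, rr 0-60 bpm, spo2 70-100 %,
    pr 30-180 bpm.
    """
    cfg = config if config is not None else default_config(mode)
    etco2 = np.arange(0.0, 101.0) if etco2 is None else np.asarray(etco2, float)
    rr = np.arange(0.0, 61.0) if rr is None else np.asarray(rr, float)
    spo2 = np.arange(70.0, 101.0) if spo2 is None else np.asarray(spo2, float)
    pr = np.arange(30.0, 181.0) if pr is None else np.asarray(pr, float)

    g_c = cfg.partition("etco2").fuzzify_array(etco2)
    g_r = cfg.partition("rr").fuzzify_array(rr)
    g_s = cfg.partition("spo2").fuzzify_array(spo2)
    g_p = cfg.partition("pr").fuzzify_array(pr)

    g_c3 = {lab: v[:, None, None] for lab, v in g_c.items()}
    g_r3 = {lab: v[None, :, None] for lab, v in g_r.items()}
    g_s3 = {lab: v[None, None, :] for lab, v in g_s.items()}
    act = _activation_arrays(cfg, g_r3, g_c3, g_s3)
    raw = _centroid_arrays(cfg, act)            # (n_etco2, n_rr, n_spo2)

    g_c2 = {lab: v[:, None, None] for lab, v in g_c.items()}
    g_r2 = {lab: v[None, :, None] for lab, v in g_r.items()}
    g_p2 = {lab: v[None, None, :] for lab, v in g_p.items()}
    amount = np.broadcast_to(
        _pr_amount_arrays(cfg, g_c2, g_r2, g_p2),
        (len(etco2), len(rr), len(pr)))         # (n_etco2, n_rr, n_pr)

    imin, imax = 10, 1
    for i in range(len(etco2)):                 # chunk over the PetCO2 axis
        adjusted = np.maximum(1.0, raw[i][:, :, None] - amount[i][:, None, :])
        ipi = np.clip(_round_half_up(adjusted), 1, 10)
        imin = min(imin, int(ipi.min()))
        imax = max(imax, int(ipi.max()))
    n = len(etco2) * len(rr) * len(spo2) * len(pr)
    return imin, imax, n
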