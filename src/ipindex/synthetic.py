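"""Seeded synthetic vital-sign streams with exact ground truth.

The generator emulates continuous 1 Hz four-channel recordings: each
channel is a constant physiological baseline plus Gaussian noise
(clamped to the physical range), and scripted respiratory-compromise
episodes override the relevant channels with constant values chosen to
satisfy the corresponding event definition with margin:

    apnea                            etco2 = 0, rr = 0
    severe_hypoxia                   spo2 = 80
    bradypneic_hypovent_hypoxia      etco2 = 55, rr = 6.5, spo2 = 87
    nonbradypneic_hypovent_hypoxia   etco2 = 25, rr = 10, spo2 = 87
    hypoxia                          spo2 = 87.5

Optional linear ramps of ``ramp_s`` seconds flank each episode; ramps
are excluded from the ground-truth intervals (the condition is not
guaranteed mid-transition), so detected events may extend into ramps
but always contain their ground-truth interval. Default noise SDs
(etco2 1.5 mmHg, rr 0.8 /min, spo2 0.6 %, pr 2.0 /min) are small enough
that baselines never cross event thresholds, keeping the bookkeeping
unambiguous. One shared seed drives four independent per-channel
substreams, so adding an episode on one channel never perturbs another.

``standard_benchmark`` builds the fixed 20-stream x 30-min evaluation
set (episode census in its manifest) used by the reliability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .engine import AgeMode, CHANNELS, VitalStream, default_partitions
from .errors import ScenarioError
from .events import ClinicalEvent

__all__ = [
    "EPISODE_KINDS",
    "EpisodeSpec",
    "ScenarioSpec",
    "GroundTruth",
    "generate",
    "standard_benchmark",
    "benchmark_scenarios",
    "benchmark_manifest",
    "DEFAULT_BASELINES",
    "DEFAULT_NOISE_SD",
]

# Channel overrides per episode kind.
EPISODE_KINDS: dict[str, dict[str, float]] = {
    "apnea": {"etco2": 0.0, "rr": 0.0},
    "severe_hypoxia": {"spo2": 80.0},
    "bradypneic_hypovent_hypoxia": {"etco2": 55.0, "rr": 6.5, "spo2": 87.0},
    "nonbradypneic_hypovent_hypoxia": {"etco2": 25.0, "rr": 10.0, "spo2": 87.0},
    "hypoxia": {"spo2": 87.5},
}

# Ground-truth event kinds implied by an episode of a given duration.
_TRUTH_RULES: dict[str, list[tuple[str, int]]] = {
    "apnea": [("severe_apnea", 30), ("cs_apnea", 15)],
    "severe_hypoxia": [("severe_hypoxia", 15), ("cs_hypoxia", 15)],
    "bradypneic_hypovent_hypoxia": [
        ("cs_bradypneic_hypovent_hypoxia", 15), ("cs_hypoxia", 15)],
    "nonbradypneic_hypovent_hypoxia": [
        ("cs_nonbradypneic_hypovent_hypoxia", 15), ("cs_hypoxia", 15)],
    "hypoxia": [("cs_hypoxia", 15)],
}

DEFAULT_BASELINES: dict[AgeMode, dict[str, float]] = {
    AgeMode.ADULT: {"etco2": 38.0, "rr": 14.0, "spo2": 98.0, "pr": 72.0},
    AgeMode.PED_1_3: {"etco2": 38.0, "rr": 28.0, "spo2": 98.0, "pr": 120.0},
    AgeMode.PED_3_6: {"etco2": 38.0, "rr": 26.0, "spo2": 98.0, "pr": 110.0},
    AgeMode.PED_6_12: {"etco2": 38.0, "rr": 22.0, "spo2": 98.0, "pr": 95.0},
}
DEFAULT_NOISE_SD = {"etco2": 1.5, "rr": 0.8, "spo2": 0.6, "pr": 2.0}

GroundTruth = list[ClinicalEvent]


@dataclass(frozen=True)
class EpisodeSpec:
    """One scripted episode: [onset_s, onset_s + duration_s) at the
    override values, flanked by linear ramps of ``ramp_s`` seconds."""

    kind: str
    onset_s: int
    duration_s: int
    ramp_s: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EPISODE_KINDS:
            raise ScenarioError(
                f"unknown episode kind {self.kind!r}; "
                f"expected one of {sorted(EPISODE_KINDS)}")
        if self.duration_s <= 0 or self.onset_s < 0 or self.ramp_s < 0:
            raise ScenarioError(f"invalid episode timing: {self}")

    @property
    def end_s(self) -> int:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class ScenarioSpec:
    duration_s: int = 600
    mode: AgeMode = AgeMode.ADULT
    baselines: Mapping[str, float] | None = None
    noise_sd: Mapping[str, float] | None = None
    episodes: tuple[EpisodeSpec, ...] = ()
    seed: int = 0

    def resolved_baselines(self) -> dict[str, float]:
        base = dict(DEFAULT_BASELINES[AgeMode.coerce(self.mode)])
        if self.baselines:
            base.update(self.baselines)
        return base

    def resolved_noise_sd(self) -> dict[str, float]:
        sd = dict(DEFAULT_NOISE_SD)
        if self.noise_sd:
            sd.update(self.noise_sd)
        return sd


def _validate(spec: ScenarioSpec) -> None:
    parts = default_partitions(spec.mode)
    base = spec.resolved_baselines()
    for ch in CHANNELS:
        if parts[ch]["N"].grade(base[ch]) != 1.0:
            raise ScenarioError(
                f"baseline {ch}={base[ch]} is outside the N plateau of "
                f"mode {AgeMode.coerce(spec.mode).value}")
    eps = sorted(spec.episodes, key=lambda e: e.onset_s)
    for ep in eps:
        if ep.onset_s - ep.ramp_s < 0 or ep.end_s + ep.ramp_s > spec.duration_s:
            raise ScenarioError(f"episode (incl. ramps) outside stream: {ep}")
    for a, b in zip(eps[:-1], eps[1:]):
        if a.end_s + a.ramp_s > b.onset_s - b.ramp_s:
            raise ScenarioError(
                f"episodes overlap after ramps: {a.kind}@{a.onset_s} and "
                f"{b.kind}@{b.onset_s}")


def generate(spec: ScenarioSpec) -> tuple[VitalStream, GroundTruth]:
    """Emit the 1 Hz stream and its provable ground-truth events.

    Identical spec (including seed) yields a bit-identical stream; each
    ground-truth interval satisfies its event condition at every grid
    second by construction (episode seconds are noise-free overrides).
    """
    _validate(spec)
    n = int(spec.duration_s)
    base = spec.resolved_baselines()
    sd = spec.resolved_noise_sd()
    parts = default_partitions(spec.mode)
    substreams = np.random.SeedSequence(spec.seed).spawn(len(CHANNELS))
    data: dict[str, np.ndarray] = {}
    for ch, ss in zip(CHANNELS, substreams):
        rng = np.random.default_rng(ss)
        lo, hi = parts[ch].domain
        data[ch] = np.clip(base[ch] + rng.normal(0.0, sd[ch], size=n), lo, hi)

    truth: GroundTruth = []
    for ep in sorted(spec.episodes, key=lambda e: e.onset_s):
        for ch, value in EPISODE_KINDS[ep.kind].items():
            arr = data[ch]
            arr[ep.onset_s:ep.end_s] = value
            if ep.ramp_s:
                down = np.linspace(base[ch], value, ep.ramp_s + 2)[1:-1]
                arr[ep.onset_s - ep.ramp_s:ep.onset_s] = down
                arr[ep.end_s:ep.end_s + ep.ramp_s] = down[::-1]
        for kind, min_s in _TRUTH_RULES[ep.kind]:
            if ep.duration_s >= min_s:
                truth.append(ClinicalEvent(ep.onset_s, ep.end_s, kind))

    stream = VitalStream(
        t=np.arange(n, dtype=float), mode=spec.mode,
        etco2=data["etco2"], rr=data["rr"], spo2=data["spo2"], pr=data["pr"])
    return stream, sorted(truth)


# ---------------------------------------------------------------------------
# Standard benchmark: 20 streams x 30 min

_BENCH_N_STREAMS = 20
_BENCH_DURATION_S = 1800
_BENCH_N_CONTROLS = 5
_BENCH_CYCLE = (
    EpisodeSpec("apnea", 0, 40),
    EpisodeSpec("severe_hypoxia", 0, 20),
    EpisodeSpec("bradypneic_hypovent_hypoxia", 0, 25),
    EpisodeSpec("nonbradypneic_hypovent_hypoxia", 0, 25),
    EpisodeSpec("hypoxia", 0, 20),
)
_BENCH_ONSETS = (300, 1200)


def benchmark_scenarios(seed: int = 0) -> list[ScenarioSpec]:
    """Fixed benchmark layout: 5 event-free controls + 15 streams with
    two episodes each (kinds cycling so every kind occurs 6 times).
    Only the channel noise depends on ``seed``."""
    children = np.random.SeedSequence(seed).generate_state(_BENCH_N_STREAMS)
    specs = []
    for i in range(_BENCH_N_STREAMS):
        episodes: tuple[EpisodeSpec, ...] = ()
        if i >= _BENCH_N_CONTROLS:
            j = i - _BENCH_N_CONTROLS
            episodes = tuple(
                replace(_BENCH_CYCLE[(j + k) % len(_BENCH_CYCLE)], onset_s=onset)
                for k, onset in enumerate(_BENCH_ONSETS))
        specs.append(ScenarioSpec(
            duration_s=_BENCH_DURATION_S, mode=AgeMode.ADULT,
            episodes=episodes, seed=int(children[i]) & 0x7FFFFFFF))
    return specs


def standard_benchmark(seed: int = 0) -> list[tuple[VitalStream, GroundTruth]]:
    """Generate the 20-stream benchmark (36,000 s total)."""
    return [generate(spec) for spec in benchmark_scenarios(seed)]


def benchmark_manifest(seed: int = 0) -> dict:
    """Episode census and layout of the standard benchmark."""
    specs = benchmark_scenarios(seed)
    census: dict[str, int] = {k: 0 for k in EPISODE_KINDS}
    truth_census: dict[str, int] = {}
    for spec in specs:
        for ep in spec.episodes:
            census[ep.kind] += 1
            for kind, min_s in _TRUTH_RULES[ep.kind]:
                if ep.duration_s >= min_s:
                    truth_census[kind] = truth_census.get(kind, 0) + 1
    return {
        "seed": seed,
        "n_streams": len(specs),
        "duration_s": _BENCH_DURATION_S,
        "total_s": len(specs) * _BENCH_DURATION_S,
        "n_controls": _BENCH_N_CONTROLS,
        "episode_census": census,
        "ground_truth_census": dict(sorted(truth_census.items())),
        "stream_seeds": [spec.seed for spec in specs],
    }
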