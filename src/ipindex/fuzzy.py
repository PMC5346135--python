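"""Mamdani-style fuzzy inference primitives.

The building blocks are deliberately generic: trapezoidal membership
functions grouped into *sum-to-one* partitions (every crisp value splits
its unit membership mass between at most two adjacent labels, realizing
the "gray area" of partial membership between ranges), rules that combine
antecedent grades with ``min`` (AND) and aggregate per consequent with
``max`` (OR / aggregation), and centroid-of-area defuzzification over
triangular output sets.

The output sets are symmetric triangles of half-width 0.5 centred on the
integer levels 1..10 of the output universe [0.5, 10.5]. Their supports
are pairwise disjoint, so the centroid of the pointwise maximum of the
activation-clipped triangles has the closed form

    centroid = sum_k k * h_k (2 - h_k)  /  sum_k h_k (2 - h_k)

where ``h_k`` is the activation of level ``k`` (the area of a unit
triangle clipped at height ``h`` is proportional to ``h (2 - h)`` and its
centroid stays at the triangle centre by symmetry). Tests cross-check
this against dense numerical integration of the aggregated curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidSampleError, NoRuleFiredError

__all__ = [
    "TrapezoidMF",
    "FuzzyPartition",
    "FuzzyRule",
    "TriangularConsequents",
    "membership_grade",
    "fuzzify",
    "evaluate_rules",
    "defuzzify_centroid",
]


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoidal membership function with breakpoints a <= b <= c <= d.

    Rises linearly on (a, b), is 1 on [b, c], falls linearly on (c, d) and
    is 0 outside (a, d). ``a == b`` / ``c == d`` produce shoulder or
    triangular shapes.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        pts = (self.a, self.b, self.c, self.d)
        if not all(np.isfinite(pts)):
            raise ConfigurationError(f"non-finite trapezoid breakpoints: {pts}")
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(f"trapezoid breakpoints must be ordered: {pts}")

    def grade(self, x):
        """Membership grade in [0, 1]; accepts scalars or arrays."""
        arr = np.asarray(x, dtype=float)
        g = np.where((arr >= self.b) & (arr <= self.c), 1.0, 0.0)
        if self.b > self.a:
            rising = (arr > self.a) & (arr < self.b)
            g = np.where(rising, (arr - self.a) / (self.b - self.a), g)
        if self.d > self.c:
            falling = (arr > self.c) & (arr < self.d)
            g = np.where(falling, (self.d - arr) / (self.d - self.c), g)
        return g if g.ndim else float(g)

    @property
    def support(self) -> tuple[float, float]:
        return (self.a, self.d)


def membership_grade(mf: TrapezoidMF, x) -> float:
    """Evaluate a trapezoidal membership function (total, continuous)."""
    return mf.grade(x)


@dataclass(frozen=True)
class FuzzyPartition:
    """An ordered family of trapezoids covering one parameter's range.

    The chaining constraints enforced here (each trapezoid's falling edge
    coincides with the next one's rising edge; the first/last are
    shoulders pinned to the range ends) guarantee that grades sum to one
    everywhere in the declared range, that adjacent functions overlap and
    that non-adjacent functions have disjoint support.
    """

    name: str
    functions: tuple[tuple[str, TrapezoidMF], ...]

    def __post_init__(self) -> None:
        fs = self.functions
        if len(fs) < 2:
            raise ConfigurationError(f"partition {self.name!r} needs >= 2 sets")
        labels = [lab for lab, _ in fs]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate labels in partition {self.name!r}")
        first, last = fs[0][1], fs[-1][1]
        if first.a != first.b:
            raise ConfigurationError(
                f"{self.name}: first set must be a left shoulder (a == b)")
        if last.c != last.d:
            raise ConfigurationError(
                f"{self.name}: last set must be a right shoulder (c == d)")
        for (l1, m1), (l2, m2) in zip(fs[:-1], fs[1:]):
            if not (m1.c == m2.a and m1.d == m2.b):
                raise ConfigurationError(
                    f"{self.name}: transition {l1}->{l2} must share edges "
                    f"(c1,d1)=({m1.c},{m1.d}) vs (a2,b2)=({m2.a},{m2.b})")
            if not m1.d > m1.c:
                raise ConfigurationError(
                    f"{self.name}: transition {l1}->{l2} must have positive width")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.functions)

    @property
    def domain(self) -> tuple[float, float]:
        return (self.functions[0][1].a, self.functions[-1][1].d)

    def __getitem__(self, label: str) -> TrapezoidMF:
        for lab, mf in self.functions:
            if lab == label:
                return mf
        raise KeyError(label)

    def clamp(self, x):
        lo, hi = self.domain
        return np.clip(x, lo, hi)

    def fuzzify(self, x: float) -> dict[str, float]:
        """Grades for every label at crisp ``x`` (clamped to the range)."""
        if not np.isfinite(x):
            raise InvalidSampleError(
                f"cannot fuzzify non-finite {self.name} value: {x!r}")
        xc = float(self.clamp(x))
        return {lab: float(mf.grade(xc)) for lab, mf in self.functions}

    def fuzzify_array(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Vectorized :meth:`fuzzify`; caller is responsible for masking
        non-finite entries (they propagate as NaN grades)."""
        xc = self.clamp(np.asarray(x, dtype=float))
        return {lab: mf.grade(xc) for lab, mf in self.functions}


def fuzzify(x: float, partition: FuzzyPartition) -> dict[str, float]:
    """Map a crisp value to per-label membership grades (sum to 1)."""
    return partition.fuzzify(x)


@dataclass(frozen=True)
class FuzzyRule:
    """IF (param is label) AND ... THEN (output is ``consequent``).

    Parameters absent from the antecedent are "don't care".
    """

    antecedent: tuple[tuple[str, str], ...]
    consequent: int

    def __init__(self, antecedent, consequent: int):
        if isinstance(antecedent, Mapping):
            antecedent = tuple(antecedent.items())
        object.__setattr__(self, "antecedent", tuple(antecedent))
        object.__setattr__(self, "consequent", int(consequent))
        if not 1 <= self.consequent <= 10:
            raise ConfigurationError(
                f"rule consequent must be in 1..10, got {consequent}")

    def activation(self, grades: Mapping[str, Mapping[str, float]]) -> float:
        a = 1.0
        for param, label in self.antecedent:
            if param not in grades:
                raise ConfigurationError(f"rule references unknown parameter {param!r}")
            pg = grades[param]
            if label not in pg:
                raise ConfigurationError(
                    f"rule references unknown label {label!r} for parameter {param!r}")
            a = min(a, pg[label])
        return a


def evaluate_rules(
    grades: Mapping[str, Mapping[str, float]],
    rules: Sequence[FuzzyRule],
) -> dict[int, float]:
    """Min/max Mamdani rule evaluation.

    Rule activation is the ``min`` over its antecedent grades; the
    activation of each consequent level is the ``max`` over all rules
    sharing that consequent. Levels with no firing rule report 0.
    """
    acts: dict[int, float] = {r.consequent: 0.0 for r in rules}
    for rule in rules:
        a = rule.activation(grades)
        if a > acts[rule.consequent]:
            acts[rule.consequent] = a
    return acts


@dataclass(frozen=True)
class TriangularConsequents:
    """Symmetric triangular output sets centred on integer levels.

    Half-width 0.5 keeps every triangle inside the output universe
    [0.5, 10.5] (so the centroid of the *unclipped* set at level k is
    exactly k) and makes the supports pairwise disjoint, which is what
    licenses the closed-form centroid used in :meth:`centroid`.
    """

    levels: tuple[int, ...] = tuple(range(1, 11))
    half_width: float = 0.5
    lo: float = 0.5
    hi: float = 10.5

    def __post_init__(self) -> None:
        lv = sorted(self.levels)
        for k in lv:
            if k - self.half_width < self.lo or k + self.half_width > self.hi:
                raise ConfigurationError(
                    f"consequent triangle at {k} exceeds universe [{self.lo}, {self.hi}]")
        if any(b - a < 2 * self.half_width for a, b in zip(lv[:-1], lv[1:])):
            raise ConfigurationError("consequent triangles must not overlap")

    def membership(self, level: int, y):
        """Unclipped triangle for ``level`` evaluated on ``y`` (for plots
        and for the numerical-integration oracle in the tests)."""
        y = np.asarray(y, dtype=float)
        return np.clip(1.0 - np.abs(y - level) / self.half_width, 0.0, None)

    def clipped_area(self, h):
        """Area of a triangle clipped at activation ``h`` (array-safe)."""
        return self.half_width * h * (2.0 - h)

    def centroid(self, activations: Mapping[int, float]) -> float:
        num = 0.0
        den = 0.0
        for k in sorted(activations):
            if k not in self.levels:
                raise ConfigurationError(f"activation for unknown output level {k}")
            h = min(max(float(activations[k]), 0.0), 1.0)
            w = self.clipped_area(h)
            num += k * w
            den += w
        if den <= 0.0:
            raise NoRuleFiredError("all consequent activations are zero")
        lo, hi = min(self.levels), max(self.levels)
        return float(np.clip(num / den, lo, hi))


def defuzzify_centroid(
    activations: Mapping[int, float],
    consequents: TriangularConsequents | None = None,
) -> float:
    """Centroid of area of the aggregated (max of clipped) output sets.

    Raises :class:`NoRuleFiredError` when every activation is zero; the
    result lies in [1, 10].
    """
    if consequents is None:
        consequents = TriangularConsequents()
    return consequents.centroid(activations)
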