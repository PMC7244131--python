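"""Trapezoidal fuzzy membership scoring and law-of-the-minimum combination.

Each environmental criterion carries a four-threshold trapezoidal response:
score 0 outside the absolute range, 100 inside the optimal range, and linear
ramps between.  A record's overall suitability is the minimum of its
per-criterion scores (the most limiting criterion governs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from cropsuit.errors import FuzzySetError, InputError

#: Canonical criterion names, in reporting order.
CRITERIA: tuple[str, ...] = (
    "temperature",
    "rainfall",
    "solar_radiation",
    "soil_ph",
    "drainage_class",
)


@dataclass(frozen=True)
class FuzzySet:
    """Four thresholds defining one criterion's trapezoidal suitability response.

    Parameters
    ----------
    abs_min, opt_min, opt_max, abs_max
        Absolute and optimal range bounds in criterion units.  Must satisfy
        ``abs_min <= opt_min <= opt_max <= abs_max`` and all be finite.
        Degenerate ramps (equal adjacent thresholds) are permitted; the
        optimal branch takes precedence at a shared bound.
    """

    abs_min: float
    opt_min: float
    opt_max: float
    abs_max: float

    def violations(self) -> list[str]:
        """Return human-readable descriptions of every invariant breach (empty if valid)."""
        problems: list[str] = []
        vals = (self.abs_min, self.opt_min, self.opt_max, self.abs_max)
        for name, v in zip(("abs_min", "opt_min", "opt_max", "abs_max"), vals):
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise InputError(f"{name} must be numeric, got {type(v).__name__}")
            if not math.isfinite(v):
                problems.append(f"{name} is not finite ({v!r})")
        if problems:
            return problems
        if self.abs_min > self.opt_min:
            problems.append(f"abs_min ({self.abs_min}) > opt_min ({self.opt_min})")
        if self.opt_min > self.opt_max:
            problems.append(f"opt_min ({self.opt_min}) > opt_max ({self.opt_max})")
        if self.opt_max > self.abs_max:
            problems.append(f"opt_max ({self.opt_max}) > abs_max ({self.abs_max})")
        return problems

    def validate(self) -> None:
        """Raise :class:`FuzzySetError` if the set is invalid."""
        problems = self.violations()
        if problems:
            raise FuzzySetError("; ".join(problems))

    @property
    def is_valid(self) -> bool:
        return not self.violations()


def validate_fuzzy_set(s: FuzzySet) -> list[str]:
    """Check threshold ordering and finiteness; return a (possibly empty) violation report."""
    return s.violations()


def membership(p: float | np.ndarray, s: FuzzySet) -> float | np.ndarray:
    """Evaluate the trapezoidal membership of value(s) ``p`` in fuzzy set ``s``.

    Piecewise-linear response on a 0-100 scale:

    * ``p < abs_min`` or ``p > abs_max`` -> 0
    * ``abs_min <= p < opt_min`` -> linear ramp up to 100
    * ``opt_min <= p < opt_max`` -> 100
    * ``opt_max <= p < abs_max`` -> linear ramp down to 0
    * ``p == abs_max`` -> 0 (both adjacent branches agree), except when
      ``opt_max == abs_max`` (degenerate ramp), where the optimal branch wins
      and the score is 100.

    Accepts a scalar or a numpy array; non-finite entries raise.
    """
    s.validate()
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("membership input contains non-finite values")

    out = np.zeros(arr.shape, dtype=float)

    plateau = (arr >= s.opt_min) & (arr < s.opt_max)
    # Degenerate upper ramp: opt_max == abs_max scores 100 at the shared bound.
    plateau |= (arr == s.opt_max) & (s.opt_max == s.abs_max)
    out[plateau] = 100.0

    if s.opt_min > s.abs_min:
        up = (arr >= s.abs_min) & (arr < s.opt_min)
        out[up] = (arr[up] - s.abs_min) / (s.opt_min - s.abs_min) * 100.0

    if s.abs_max > s.opt_max:
        down = (arr >= s.opt_max) & (arr < s.abs_max) & ~plateau
        out[down] = (1.0 - (arr[down] - s.opt_max) / (s.abs_max - s.opt_max)) * 100.0

    if arr.ndim == 0:
        return float(out)
    return out


def combine_min(scores: Iterable[float]) -> float:
    """Combine per-criterion scores by the law of the minimum.

    Returns NaN (the nodata marker for scalar scores) if any input is NaN:
    a record with an unknown criterion cannot be scored.
    """
    vals = [float(v) for v in scores]
    if not vals:
        raise InputError("combine_min requires at least one score")
    if any(math.isnan(v) for v in vals):
        return float("nan")
    for v in vals:
        if not (0.0 <= v <= 100.0):
            raise InputError(f"score {v} outside [0, 100]")
    return min(vals)


@dataclass(frozen=True)
class CriterionProfile:
    """One criterion's name, units, and fuzzy response within a crop profile."""

    name: str
    units: str
    set: FuzzySet


@dataclass(frozen=True)
class CropProfile:
    """Named, ordered collection of per-criterion fuzzy sets for one crop."""

    label: str
    criteria: tuple[CriterionProfile, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.criteria:
            raise InputError(f"profile {self.label!r} has no criteria")
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise InputError(f"profile {self.label!r} has duplicate criterion names")
        for c in self.criteria:
            c.set.validate()

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.criteria)

    def __getitem__(self, name: str) -> CriterionProfile:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.criterion_names


def score_record(
    values: Mapping[str, float],
    profile: CropProfile,
    excluded: Sequence[str] | set[str] = (),
) -> float:
    """Score one record: minimum of memberships over all non-excluded criteria.

    ``values`` must provide every criterion of ``profile`` not named in
    ``excluded``.  NaN criterion values propagate to a NaN score.
    """
    excluded = set(excluded)
    scores: list[float] = []
    for crit in profile.criteria:
        if crit.name in excluded:
            continue
        if crit.name not in values:
            raise InputError(f"missing value for criterion {crit.name!r}")
        v = values[crit.name]
        if math.isnan(v):
            return float("nan")
        scores.append(float(membership(v, crit.set)))
    if not scores:
        raise InputError("all criteria excluded; nothing to score")
    return combine_min(scores)
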