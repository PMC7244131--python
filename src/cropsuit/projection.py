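"""Ensemble future-suitability projection, change mapping, and area summaries.

Future climate members supply temperature and rainfall; soil and solar layers
are held at baseline.  Per-member suitability maps are averaged pixel-wise
(mean of suitabilities, not of climates).  Suitability surfaces are summarized
into integer score bins with areas in million km², and changes against a
baseline are classified as unchanged / minimally changed / changed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cropsuit.errors import AlignmentError, InputError, UndefinedStatisticError
from cropsuit.fuzzy import CropProfile
from cropsuit.raster import (
    GridLayer,
    LayerStack,
    NODATA,
    cell_areas,
    check_alignment,
    ensure_aligned,
    suitability_map,
)

#: Integer score bins partitioning [0, 100] after nearest-integer rounding.
BIN_LABELS: tuple[str, ...] = (
    "<1",
    "1-10",
    "11-20",
    "21-30",
    "31-40",
    "41-50",
    "51-60",
    "61-70",
    "71-80",
    "81-90",
    "91-100",
)

#: Group label -> slice of BIN_LABELS it aggregates.  The lowest group
#: includes the <1 bin; the reported total excludes it.
GROUPS: dict[str, tuple[int, int]] = {
    "<1 TO 30": (0, 4),
    "31 TO 70": (4, 8),
    "71 TO 100": (8, 11),
}

_MEMBER_CRITERIA = ("temperature", "rainfall")


@dataclass
class ScenarioEnsemble:
    """Per-climate-model future layer stacks for one emissions scenario."""

    scenario_label: str
    members: list[LayerStack]
    baseline: LayerStack

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError("scenario ensemble has no members")
        for k, member in enumerate(self.members):
            for crit in _MEMBER_CRITERIA:
                if crit not in member:
                    raise InputError(f"ensemble member {k} lacks a {crit!r} layer")
            merged = self.baseline.with_layers(
                **{c: member[c] for c in _MEMBER_CRITERIA}
            )
            problems = check_alignment(merged)
            if problems:
                raise AlignmentError(f"member {k} misaligned with baseline: {'; '.join(problems)}")


def ensemble_suitability(
    ens: ScenarioEnsemble,
    profile: CropProfile,
    excluded: Sequence[str] | set[str] = (),
) -> GridLayer:
    """Mean of per-member suitability maps; nodata wherever any member is nodata."""
    total = None
    invalid = None
    for member in ens.members:
        merged = ens.baseline.with_layers(**{c: member[c] for c in _MEMBER_CRITERIA})
        suit = suitability_map(merged, profile, excluded)
        vals = suit.filled(0.0)
        if total is None:
            total = vals
            invalid = suit.mask.copy()
        else:
            total += vals
            invalid |= suit.mask
    total /= len(ens.members)
    total[invalid] = NODATA
    ref = ens.baseline.first
    return GridLayer(
        values=total,
        transform=ref.transform,
        crs_kind=ref.crs_kind,
        nodata=NODATA,
        criterion="suitability",
        units="score",
    )


def round_scores(values: np.ndarray) -> np.ndarray:
    """Nearest-integer rounding (half away from zero) used for binning."""
    return np.floor(np.asarray(values, dtype=float) + 0.5)


def _bin_index(rounded: np.ndarray) -> np.ndarray:
    """Map rounded integer scores to bin indices: {0} -> 0, [1,10] -> 1, ... [91,100] -> 10."""
    idx = np.where(rounded < 1, 0, ((rounded - 1) // 10 + 1).astype(int))
    return idx.astype(int)


@dataclass
class AreaTable:
    """Per-bin suitability areas (million km²) with group and total aggregates.

    Groups sum their constituent bins; the total sums every bin except <1.
    """

    bins: dict[str, float]

    def __post_init__(self) -> None:
        missing = [b for b in BIN_LABELS if b not in self.bins]
        if missing:
            raise InputError(f"area table missing bin(s) {missing}")

    @property
    def groups(self) -> dict[str, float]:
        vals = [self.bins[b] for b in BIN_LABELS]
        return {g: float(sum(vals[i:j])) for g, (i, j) in GROUPS.items()}

    @property
    def total(self) -> float:
        return float(sum(self.bins[b] for b in BIN_LABELS[1:]))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"row": "Total", "area_mkm2": self.total}]
        rows += [{"row": b, "area_mkm2": self.bins[b]} for b in BIN_LABELS]
        rows += [{"row": g, "area_mkm2": v} for g, v in self.groups.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_bin_values(cls, values: Sequence[float]) -> "AreaTable":
        if len(values) != len(BIN_LABELS):
            raise InputError(f"expected {len(BIN_LABELS)} bin values, got {len(values)}")
        return cls(bins=dict(zip(BIN_LABELS, map(float, values))))


def bin_areas(suit: GridLayer) -> AreaTable:
    """Sum cell areas per integer score bin; result in million km²."""
    valid = ~suit.mask
    scores = suit.values[valid]
    if scores.size and (scores.min() < 0 or scores.max() > 100):
        raise InputError("suitability scores outside [0, 100]")
    areas = cell_areas(suit)[valid]
    idx = _bin_index(round_scores(scores))
    sums = np.bincount(idx, weights=areas, minlength=len(BIN_LABELS)) / 1e6
    return AreaTable.from_bin_values(sums)


def _round_percent(x: float) -> int:
    # Report at whole-percent precision via a 0.1%-quantized intermediate
    # (half-to-even at the final step), matching printed-table conventions.
    return int(round(round(x, 1)))


def percent_change(table_future: AreaTable, table_baseline: AreaTable) -> dict[str, dict]:
    """Percent change in total, moderate (31-70), and high (71-100) area.

    Returns ``{metric: {"percent": float, "rounded": int}}``; a zero baseline
    yields NaN / None for that metric.
    """
    pairs = {
        "total": (table_future.total, table_baseline.total),
        "moderate": (table_future.groups["31 TO 70"], table_baseline.groups["31 TO 70"]),
        "high": (table_future.groups["71 TO 100"], table_baseline.groups["71 TO 100"]),
    }
    out: dict[str, dict] = {}
    for name, (fut, base) in pairs.items():
        if base == 0.0:
            out[name] = {"percent": math.nan, "rounded": None}
        else:
            pct = 100.0 * (fut - base) / base
            out[name] = {"percent": pct, "rounded": _round_percent(pct)}
    return out


@dataclass
class ChangeSummary:
    """Future-minus-baseline suitability change with unchanged/minimal fractions.

    "Unchanged" means |Δ| < 0.5 (indistinguishable at integer reporting
    precision); "minimally changed" means 0.5 <= |Δ| <= 10.  Fractions are
    reported against both the both-valid (intersection) and either-valid
    (union) denominators; pixels valid on only one side count as changed.
    """

    delta: GridLayer
    unchanged_fraction: float
    minimal_fraction: float
    unchanged_fraction_union: float
    minimal_fraction_union: float
    unchanged_area_km2: float
    minimal_area_km2: float
    valid_area_km2: float


def change_map(future: GridLayer, baseline: GridLayer) -> ChangeSummary:
    """Pixel-wise suitability change and its unchanged/minimal summary."""
    problems = check_alignment(LayerStack({"future": future, "baseline": baseline}))
    if problems:
        raise AlignmentError("; ".join(problems))
    both = ~future.mask & ~baseline.mask
    either = ~future.mask | ~baseline.mask
    if not both.any():
        raise InputError("no pixels valid in both layers")
    delta_vals = np.full(future.shape, NODATA)
    delta_vals[both] = future.values[both] - baseline.values[both]
    delta = future.grid_like(delta_vals, criterion="suitability_change", nodata=NODATA)

    areas = cell_areas(future)
    absd = np.abs(delta_vals)
    unchanged = both & (absd < 0.5)
    minimal = both & (absd >= 0.5) & (absd <= 10.0)
    a_both = float(areas[both].sum())
    a_either = float(areas[either].sum())
    a_unchanged = float(areas[unchanged].sum())
    a_minimal = float(areas[minimal].sum())
    return ChangeSummary(
        delta=delta,
        unchanged_fraction=a_unchanged / a_both,
        minimal_fraction=a_minimal / a_both,
        unchanged_fraction_union=a_unchanged / a_either,
        minimal_fraction_union=a_minimal / a_either,
        unchanged_area_km2=a_unchanged,
        minimal_area_km2=a_minimal,
        valid_area_km2=a_both,
    )


def mean_suitability(suit: GridLayer) -> float:
    """Area-weighted mean score over valid pixels."""
    valid = ~suit.mask
    if not valid.any():
        raise UndefinedStatisticError("mean suitability undefined: no valid pixels")
    areas = cell_areas(suit)[valid]
    return float(np.average(suit.values[valid], weights=areas))


def crosstab_categorical(reference: GridLayer, suit: GridLayer) -> pd.DataFrame:
    """Cross-tabulate a 3-class reference model against a suitability surface.

    Reference classes are 0 (unsuitable), 1 (suitable), 2 (best).  One row per
    class: total area (km²), area per score bin, fraction of class area with
    score >= 90, and area-weighted mean suitability.
    """
    problems = check_alignment(LayerStack({"reference": reference, "suitability": suit}))
    if problems:
        raise AlignmentError("; ".join(problems))
    both = ~reference.mask & ~suit.mask
    ref_vals = reference.values[both]
    if ref_vals.size and not np.isin(ref_vals, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(ref_vals[~np.isin(ref_vals, (0.0, 1.0, 2.0))]))
        raise InputError(f"reference layer contains invalid class value(s) {bad}")
    areas = cell_areas(reference)
    rows = []
    for cls in (0, 1, 2):
        sel = both & (reference.values == cls)
        a_cls = float(areas[sel].sum())
        row: dict = {"class": cls, "area_km2": a_cls}
        scores = suit.values[sel]
        w = areas[sel]
        idx = _bin_index(round_scores(scores)) if scores.size else np.array([], dtype=int)
        sums = np.bincount(idx, weights=w, minlength=len(BIN_LABELS))
        for b, label in enumerate(BIN_LABELS):
            row[f"area_km2[{label}]"] = float(sums[b])
        if a_cls > 0:
            row["fraction_ge_90"] = float(w[scores >= 90.0].sum() / a_cls)
            row["mean_suitability"] = float(np.average(scores, weights=w))
        else:
            row["fraction_ge_90"] = math.nan
            row["mean_suitability"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
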