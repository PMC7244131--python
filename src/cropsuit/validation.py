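"""Producer-site validation: criterion masking and model accuracy statistics.

Modeled suitability is compared against measured productivity on the shared
0-100 scale.  Management practices neutralize criteria: irrigated sites are
scored without rainfall, soil-amended sites without pH.  Accuracy statistics
(RMSE, Nash-Sutcliffe efficiency, RMSE/SD ratio, Willmott's index of
agreement, OLS regression) are reported for the unmanaged group and for all
sites pooled, each site scored under its own mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cropsuit.errors import InputError, UndefinedStatisticError
from cropsuit.fuzzy import CropProfile, score_record
from cropsuit.raster import LayerStack


@dataclass
class ProducerSite:
    """One validation record: environment, measured productivity, management flags."""

    id: str
    measured_productivity: float
    env_values: dict[str, float] = field(default_factory=dict)
    lon: float | None = None
    lat: float | None = None
    irrigated: bool = False
    amended: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.measured_productivity <= 100.0:
            raise InputError(
                f"site {self.id!r}: measured_productivity {self.measured_productivity} "
                "outside [0, 100]"
            )


def mask_for_site(site: ProducerSite) -> set[str]:
    """Criteria excluded from scoring because management neutralizes them."""
    excluded: set[str] = set()
    if site.irrigated:
        excluded.add("rainfall")
    if site.amended:
        excluded.add("soil_ph")
    return excluded


def _site_env(site: ProducerSite, profile: CropProfile, stack: LayerStack | None) -> dict[str, float]:
    """Environment for one site: direct values take precedence over raster sampling."""
    env = dict(site.env_values)
    needed = [c for c in profile.criterion_names if c not in env]
    if needed and stack is not None and site.lon is not None and site.lat is not None:
        sampled = stack.sample(site.lon, site.lat)
        for name in needed:
            if name in sampled:
                env[name] = sampled[name]
    return env


def simulate_sites(
    sites: Sequence[ProducerSite],
    profile: CropProfile,
    stack: LayerStack | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score each site under its own criterion mask.

    Returns paired vectors ``(M, S)`` of measured productivity and simulated
    suitability, in input order.
    """
    M, S = [], []
    for site in sites:
        excluded = mask_for_site(site)
        env = _site_env(site, profile, stack)
        missing = [c for c in profile.criterion_names if c not in excluded and c not in env]
        if missing:
            raise InputError(f"site {site.id!r}: missing criterion value(s) {missing}")
        S.append(score_record(env, profile, excluded))
        M.append(site.measured_productivity)
    return np.asarray(M, dtype=float), np.asarray(S, dtype=float)


def _check_pair(M: np.ndarray, S: np.ndarray, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if M.shape != S.shape or M.ndim != 1:
        raise InputError("M and S must be 1-D vectors of equal length")
    if M.size < min_n:
        raise InputError(f"need at least {min_n} paired values, got {M.size}")
    return M, S


def rmse(M: Iterable[float], S: Iterable[float]) -> float:
    """Root mean square error, sqrt(mean((M - S)^2))."""
    M, S = _check_pair(np.asarray(list(M)), np.asarray(list(S)))
    return float(np.sqrt(np.mean((M - S) ** 2)))


def sd(M: Iterable[float]) -> float:
    """Population standard deviation (denominator n), matching the n-term error sums."""
    M = np.asarray(list(M), dtype=float)
    if M.size < 2:
        raise InputError("need at least 2 values for a standard deviation")
    return float(np.std(M, ddof=0))


def nash_sutcliffe_me(M: Iterable[float], S: Iterable[float]) -> float:
    """Nash-Sutcliffe model efficiency: 1 - SSE / SS_about_observed_mean.

    1 is a perfect fit; 0 means the observed mean predicts as well as the
    model; unbounded below.  Undefined for constant observations.
    """
    M, S = _check_pair(np.asarray(list(M)), np.asarray(list(S)))
    denom = float(np.sum((M - M.mean()) ** 2))
    if denom == 0.0:
        raise UndefinedStatisticError("model efficiency undefined: observations are constant")
    return 1.0 - float(np.sum((M - S) ** 2)) / denom


def rsr(M: Iterable[float], S: Iterable[float]) -> float:
    """RMSE / (population) standard deviation of observations; lower is better.

    With the n-denominator SD this satisfies rsr = sqrt(1 - me) exactly.
    """
    M = list(M)
    s_obs = sd(M)
    if s_obs == 0.0:
        raise UndefinedStatisticError("RSR undefined: observations are constant")
    return rmse(M, S) / s_obs


def me_from_rsr(r: float) -> float:
    """Model efficiency implied by an RMSE/SD ratio via the identity me = 1 - rsr²."""
    return 1.0 - float(r) ** 2


def willmott_ia(M: Iterable[float], S: Iterable[float]) -> float:
    """Willmott's index of agreement, in [0, 1]; 1 is a perfect fit."""
    M, S = _check_pair(np.asarray(list(M)), np.asarray(list(S)))
    mbar = M.mean()
    denom = float(np.sum((np.abs(S - mbar) + np.abs(M - mbar)) ** 2))
    if denom == 0.0:
        raise UndefinedStatisticError("index of agreement undefined: zero potential error")
    return 1.0 - float(np.sum((S - M) ** 2)) / denom


def linear_fit_r2(M: Iterable[float], S: Iterable[float]) -> dict[str, float]:
    """OLS regression of measured on simulated: r², slope, intercept, p-value."""
    M, S = _check_pair(np.asarray(list(M)), np.asarray(list(S)), min_n=3)
    if np.ptp(S) == 0.0:
        raise UndefinedStatisticError("regression undefined: simulated values are constant")
    fit = stats.linregress(S, M)
    return {
        "r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
    }


def _cv_percent(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if m == 0.0:
        return math.nan
    return 100.0 * float(np.std(x, ddof=0)) / m


@dataclass
class ValidationReport:
    """Grouped summary rows plus accuracy rows, mirroring a two-block table."""

    group_rows: list[dict]
    accuracy_rows: list[dict]

    def group_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.group_rows)

    def accuracy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracy_rows)

    def to_csv(self, path: str | Path) -> None:
        """Write both blocks to one CSV, blocks separated by a blank line."""
        with open(path, "w") as fh:
            self.group_frame().to_csv(fh, index=False)
            fh.write("\n")
            self.accuracy_frame().to_csv(fh, index=False)


_GROUP_ORDER = ((False, False), (False, True), (True, False), (True, True))


def _excluded_label(excluded: set[str]) -> str:
    if not excluded:
        return "all criteria"
    return "excluded: " + ", ".join(sorted(excluded))


def _accuracy_row(label: str, M: np.ndarray, S: np.ndarray) -> dict:
    row: dict = {"group": label, "n": int(M.size), "rmse": rmse(M, S), "sd_measured": sd(M)}
    try:
        row["me"] = nash_sutcliffe_me(M, S)
        row["rsr"] = rsr(M, S)
    except UndefinedStatisticError:
        row["me"] = math.nan
        row["rsr"] = math.nan
    try:
        row["ia"] = willmott_ia(M, S)
    except UndefinedStatisticError:
        row["ia"] = math.nan
    try:
        row.update(linear_fit_r2(M, S))
    except (UndefinedStatisticError, InputError):
        row.update({"r2": math.nan, "slope": math.nan, "intercept": math.nan, "p_value": math.nan})
    return row


def validation_report(
    sites: Sequence[ProducerSite],
    profile: CropProfile,
    stack: LayerStack | None = None,
) -> ValidationReport:
    """Grouped means/CVs by management flags plus accuracy statistics.

    Accuracy is computed for the unmanaged group (no irrigation, no
    amendment) and for all sites pooled, each site scored under its own mask.
    Empty groups are omitted.
    """
    if len(sites) < 2:
        raise InputError("need at least 2 sites for a validation report")
    M, S = simulate_sites(sites, profile, stack)

    group_rows = []
    for irr, amd in _GROUP_ORDER:
        idx = [i for i, s in enumerate(sites) if s.irrigated == irr and s.amended == amd]
        if not idx:
            continue
        m, s_sim = M[idx], S[idx]
        excluded = mask_for_site(sites[idx[0]])
        group_rows.append(
            {
                "irrigated": irr,
                "amended": amd,
                "n": len(idx),
                "mean_measured": float(m.mean()),
                "cv_measured": _cv_percent(m),
                "mean_simulated": float(s_sim.mean()),
                "cv_simulated": _cv_percent(s_sim),
                "model_used": _excluded_label(excluded),
            }
        )
    group_rows.append(
        {
            "irrigated": None,
            "amended": None,
            "n": len(sites),
            "mean_measured": float(M.mean()),
            "cv_measured": _cv_percent(M),
            "mean_simulated": float(S.mean()),
            "cv_simulated": _cv_percent(S),
            "model_used": "per-site mask",
        }
    )

    accuracy_rows = []
    nat_idx = [i for i, s in enumerate(sites) if not s.irrigated and not s.amended]
    if len(nat_idx) >= 2:
        accuracy_rows.append(_accuracy_row("natural", M[nat_idx], S[nat_idx]))
    accuracy_rows.append(_accuracy_row("all", M, S))
    return ValidationReport(group_rows=group_rows, accuracy_rows=accuracy_rows)


# --- CSV interchange -------------------------------------------------------

_SITE_COLUMNS = [
    "id",
    "lon",
    "lat",
    "temperature",
    "rainfall",
    "solar_radiation",
    "soil_ph",
    "drainage_class",
    "measured_productivity",
    "irrigated",
    "amended",
]


def read_sites_csv(path: str | Path) -> list[ProducerSite]:
    """Read producer sites from CSV.  Environmental columns may be absent if
    lon/lat are given (values are then sampled from a stack at scoring time)."""
    df = pd.read_csv(path)
    if "id" not in df.columns or "measured_productivity" not in df.columns:
        raise InputError("sites CSV requires 'id' and 'measured_productivity' columns")
    sites = []
    env_cols = [c for c in ("temperature", "rainfall", "solar_radiation", "soil_ph", "drainage_class") if c in df.columns]
    for _, row in df.iterrows():
        env = {c: float(row[c]) for c in env_cols if pd.notna(row[c])}
        sites.append(
            ProducerSite(
                id=str(row["id"]),
                measured_productivity=float(row["measured_productivity"]),
                env_values=env,
                lon=float(row["lon"]) if "lon" in df.columns and pd.notna(row["lon"]) else None,
                lat=float(row["lat"]) if "lat" in df.columns and pd.notna(row["lat"]) else None,
                irrigated=bool(int(row["irrigated"])) if "irrigated" in df.columns else False,
                amended=bool(int(row["amended"])) if "amended" in df.columns else False,
            )
        )
    return sites


def write_sites_csv(sites: Sequence[ProducerSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        row = {c: s.env_values.get(c, math.nan) for c in _SITE_COLUMNS[3:8]}
        row.update(
            id=s.id,
            lon=s.lon if s.lon is not None else math.nan,
            lat=s.lat if s.lat is not None else math.nan,
            measured_productivity=s.measured_productivity,
            irrigated=int(s.irrigated),
            amended=int(s.amended),
        )
        rows.append(row)
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, index=False)
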