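"""Synthetic input generation: gradient climates, patchy soils, perturbed
climate-model ensembles, categorical reference maps, and noisy producer sites.

The default environment mimics an island system with strong orthogonal
gradients — temperature varying north-south, rainfall east-west (with solar
radiation inversely tracking rainfall) — over patchy soil pH and drainage
fields, on a 200x200 projected grid of 50 m cells.  Every generator draws
from its own labelled substream of the master seed, so adding one generator
never perturbs another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cropsuit.errors import InputError
from cropsuit.fuzzy import CropProfile, score_record
from cropsuit.projection import ScenarioEnsemble
from cropsuit.raster import GEOGRAPHIC, GridLayer, GridTransform, LayerStack, PROJECTED
from cropsuit.validation import ProducerSite, mask_for_site


@dataclass
class SynthConfig:
    """Knobs for all synthetic generators; defaults give a full-range testbed."""

    shape: tuple[int, int] = (200, 200)
    crs_kind: str = PROJECTED
    cell_size: float = 50.0
    seed: int = 0

    temperature_range: tuple[float, float] = (12.0, 30.0)
    rainfall_range: tuple[float, float] = (200.0, 10000.0)
    solar_range: tuple[float, float] = (100.0, 190.0)
    ph_mean: float = 5.8
    ph_sd: float = 0.5
    ph_patch_scale: float = 10.0
    drainage_mean: float = 4.8
    drainage_sd: float = 1.4
    drainage_patch_scale: float = 8.0

    site_count: int = 30
    site_noise_sd: float = 5.0
    irrigation_prob: float = 0.2
    amendment_prob: float = 0.2

    ensemble_size: int = 17
    temp_offset_mean: float = 2.0
    temp_offset_sd: float = 1.0
    rain_multiplier_mean: float = 1.05
    rain_multiplier_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.shape[0] < 2 or self.shape[1] < 2:
            raise InputError("synthetic grid needs at least 2 rows and 2 columns")
        for name in ("ph_sd", "drainage_sd", "site_noise_sd", "temp_offset_sd", "rain_multiplier_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for name in ("irrigation_prob", "amendment_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InputError(f"{name} must be in [0, 1]")
        if self.ensemble_size < 1:
            raise InputError("ensemble_size must be >= 1")

    def rng(self, label: str) -> np.random.Generator:
        """Independent, reproducible substream derived from (seed, label)."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(label.encode())])
        )

    @property
    def transform(self) -> GridTransform:
        # Grid anchored at the origin, northern edge at nrows * cell_size.
        return GridTransform(0.0, self.shape[0] * self.cell_size, self.cell_size, self.cell_size)


def _patchy_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed unit-variance noise field (spatially autocorrelated patches)."""
    noise = rng.standard_normal(shape)
    if scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    s = noise.std()
    if s > 0:
        noise = (noise - noise.mean()) / s
    return noise


_UNITS = {
    "temperature": "degC",
    "rainfall": "mm/yr",
    "solar_radiation": "W/m^2",
    "soil_ph": "pH",
    "drainage_class": "class",
}


def gen_environment(cfg: SynthConfig) -> LayerStack:
    """Orthogonal temperature/rainfall gradients, inverse solar, patchy soils."""
    nrows, ncols = cfg.shape
    rng = cfg.rng("environment")

    # Temperature warms southward (row axis), rainfall increases eastward.
    t_lo, t_hi = cfg.temperature_range
    temp = np.repeat(np.linspace(t_lo, t_hi, nrows)[:, None], ncols, axis=1)
    r_lo, r_hi = cfg.rainfall_range
    rain = np.repeat(np.linspace(r_lo, r_hi, ncols)[None, :], nrows, axis=0)

    # Solar radiation inversely tracks rainfall (cloudier where wetter).
    s_lo, s_hi = cfg.solar_range
    rain_norm = (rain - r_lo) / (r_hi - r_lo) if r_hi > r_lo else np.zeros_like(rain)
    solar = s_hi - rain_norm * (s_hi - s_lo)

    ph = cfg.ph_mean + cfg.ph_sd * _patchy_field(cfg.shape, cfg.ph_patch_scale, rng)
    drain_field = cfg.drainage_mean + cfg.drainage_sd * _patchy_field(
        cfg.shape, cfg.drainage_patch_scale, rng
    )
    drainage = np.clip(np.floor(drain_field + 0.5), 1, 7)

    def layer(values: np.ndarray, criterion: str) -> GridLayer:
        return GridLayer(
            values=values,
            transform=cfg.transform,
            crs_kind=cfg.crs_kind,
            criterion=criterion,
            units=_UNITS[criterion],
        )

    return LayerStack(
        {
            "temperature": layer(temp, "temperature"),
            "rainfall": layer(rain, "rainfall"),
            "solar_radiation": layer(solar, "solar_radiation"),
            "soil_ph": layer(ph, "soil_ph"),
            "drainage_class": layer(drainage, "drainage_class"),
        }
    )


def gen_gcm_ensemble(baseline: LayerStack, cfg: SynthConfig) -> ScenarioEnsemble:
    """Perturbed climate members: temperature + offset_k, rainfall x multiplier_k."""
    rng = cfg.rng("ensemble")
    offsets = rng.normal(cfg.temp_offset_mean, cfg.temp_offset_sd, cfg.ensemble_size)
    mults = np.clip(
        rng.normal(cfg.rain_multiplier_mean, cfg.rain_multiplier_sd, cfg.ensemble_size),
        0.0,
        None,
    )
    members = []
    for k in range(cfg.ensemble_size):
        temp = baseline["temperature"]
        rain = baseline["rainfall"]
        members.append(
            LayerStack(
                {
                    "temperature": temp.grid_like(temp.filled() + offsets[k], criterion="temperature"),
                    "rainfall": rain.grid_like(rain.filled() * mults[k], criterion="rainfall"),
                }
            )
        )
    # NaN fills from masked pixels become NaN nodata in member layers.
    for member in members:
        for layer in member.layers.values():
            layer.values[np.isnan(layer.values)] = layer.nodata
    return ScenarioEnsemble(scenario_label="synthetic", members=members, baseline=baseline)


def gen_sites(
    stack: LayerStack,
    profile: CropProfile,
    cfg: SynthConfig,
) -> list[ProducerSite]:
    """Producer sites at random valid pixels: productivity = masked true score + noise."""
    rng = cfg.rng("sites")
    valid = np.ones(stack.first.shape, dtype=bool)
    for name in profile.criterion_names:
        if name not in stack:
            raise InputError(f"stack lacks criterion layer {name!r}")
        valid &= ~stack[name].mask
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise InputError("no valid pixels to place sites on")
    replace = rows.size < cfg.site_count
    pick = rng.choice(rows.size, size=cfg.site_count, replace=replace)
    irrigated = rng.random(cfg.site_count) < cfg.irrigation_prob
    amended = rng.random(cfg.site_count) < cfg.amendment_prob
    noise = rng.normal(0.0, cfg.site_noise_sd, cfg.site_count)

    t = stack.first.transform
    sites = []
    for i, p in enumerate(pick):
        r, c = int(rows[p]), int(cols[p])
        env = {name: float(stack[name].values[r, c]) for name in profile.criterion_names}
        site = ProducerSite(
            id=f"site_{i:03d}",
            measured_productivity=0.0,
            env_values=env,
            lon=t.x_origin + (c + 0.5) * t.dx,
            lat=t.y_origin - (r + 0.5) * t.dy,
            irrigated=bool(irrigated[i]),
            amended=bool(amended[i]),
        )
        true_score = score_record(env, profile, mask_for_site(site))
        site.measured_productivity = float(np.clip(true_score + noise[i], 0.0, 100.0))
        sites.append(site)
    return sites


def gen_reference_classes(
    suit: GridLayer,
    thresholds: tuple[float, float] = (1.0, 70.0),
    noise_rate: float = 0.0,
    cfg: SynthConfig | None = None,
) -> GridLayer:
    """Threshold a suitability surface into classes {0, 1, 2}, with optional
    seeded label noise emulating inter-model disagreement."""
    lo, hi = thresholds
    if not lo < hi:
        raise InputError(f"thresholds must be strictly increasing, got {thresholds}")
    if not 0.0 <= noise_rate <= 1.0:
        raise InputError("noise_rate must be in [0, 1]")
    valid = ~suit.mask
    classes = np.full(suit.shape, suit.nodata)
    classes[valid] = np.where(
        suit.values[valid] < lo, 0.0, np.where(suit.values[valid] < hi, 1.0, 2.0)
    )
    if noise_rate > 0:
        rng = (cfg or SynthConfig()).rng("reference")
        flip = valid & (rng.random(suit.shape) < noise_rate)
        shift = rng.integers(1, 3, size=suit.shape)  # move to one of the two other classes
        classes[flip] = (classes[flip] + shift[flip]) % 3
    return suit.grid_like(classes, criterion="reference_class", units="class")
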