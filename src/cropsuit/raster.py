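"""Georeferenced raster layers and per-pixel suitability evaluation.

Conventions: row 0 is the northernmost row, coordinates refer to cell edges
(area/pixel-is-area registration, half-open cells), and layers on different
grids are rejected rather than resampled — grid harmonization is upstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

from cropsuit.errors import AlignmentError, InputError, RasterIOError
from cropsuit.fuzzy import CropProfile, membership

#: Default nodata sentinel for suitability outputs.
NODATA = -9999.0

#: Authalic Earth radius, km.
EARTH_RADIUS_KM = 6371.0072

GEOGRAPHIC = "geographic"
PROJECTED = "projected"

# TIFF tag codes used for georeferencing and metadata.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_METADATA = 42112
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """Affine north-up grid georeferencing.

    ``x_origin``/``y_origin`` are the west and north edges of the grid;
    ``dx``/``dy`` are positive cell width and height.  Row ``i`` covers
    ``[y_origin - (i+1)*dy, y_origin - i*dy)``; column ``j`` covers
    ``[x_origin + j*dx, x_origin + (j+1)*dx)``.
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise InputError("transform cell sizes must be nonzero")
        if self.dx < 0 or self.dy < 0:
            raise InputError("cell sizes must be positive (north-up convention)")

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        col = int(math.floor((x - self.x_origin) / self.dx))
        row = int(math.floor((self.y_origin - y) / self.dy))
        return row, col

    def row_edges(self, nrows: int) -> np.ndarray:
        """North-to-south y coordinates of the nrows+1 horizontal cell edges."""
        return self.y_origin - self.dy * np.arange(nrows + 1)


@dataclass
class GridLayer:
    """One georeferenced raster of a single environmental criterion or score."""

    values: np.ndarray
    transform: GridTransform
    crs_kind: str = PROJECTED
    nodata: float = NODATA
    criterion: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise InputError("layer values must be a non-empty 2-D array")
        if self.crs_kind not in (GEOGRAPHIC, PROJECTED):
            raise InputError(f"crs_kind must be {GEOGRAPHIC!r} or {PROJECTED!r}")
        bad = ~np.isfinite(self.values) & ~np.isnan(self.values)
        if bad.any():
            raise InputError("layer contains non-finite values other than NaN nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the pixel is nodata."""
        return np.isnan(self.values) | (self.values == self.nodata)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def filled(self, fill: float = math.nan) -> np.ndarray:
        """Values with nodata pixels replaced by ``fill``."""
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def sample(self, x: float, y: float) -> float:
        """Nearest-cell value at point (x, y); NaN if outside or nodata."""
        row, col = self.transform.cell_index(x, y)
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            return math.nan
        if self.mask[row, col]:
            return math.nan
        return float(self.values[row, col])

    def grid_like(self, values: np.ndarray, **overrides) -> "GridLayer":
        """New layer on this layer's grid with different values/metadata."""
        layer = replace(self, values=np.asarray(values, dtype=float))
        for k, v in overrides.items():
            setattr(layer, k, v)
        layer.__post_init__()
        return layer


@dataclass
class LayerStack:
    """Criterion name -> GridLayer mapping; all layers expected on one grid."""

    layers: dict[str, GridLayer] = field(default_factory=dict)

    def __getitem__(self, name: str) -> GridLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def first(self) -> GridLayer:
        return next(iter(self.layers.values()))

    def sample(self, x: float, y: float) -> dict[str, float]:
        """Nearest-cell values of every layer at point (x, y)."""
        return {name: layer.sample(x, y) for name, layer in self.layers.items()}

    def with_layers(self, **replacements: GridLayer) -> "LayerStack":
        merged = dict(self.layers)
        merged.update(replacements)
        return LayerStack(merged)


def check_alignment(stack: LayerStack) -> list[str]:
    """Report every layer whose shape/transform/crs differs from the first layer's.

    Returns an empty list when the stack is aligned.
    """
    if not stack.layers:
        raise InputError("empty layer stack")
    names = list(stack.layers)
    ref = stack.layers[names[0]]
    report: list[str] = []
    for name in names[1:]:
        layer = stack.layers[name]
        if layer.shape != ref.shape:
            report.append(f"layer {name!r}: shape {layer.shape} != {ref.shape}")
        if layer.transform != ref.transform:
            report.append(f"layer {name!r}: transform differs from {names[0]!r}")
        if layer.crs_kind != ref.crs_kind:
            report.append(f"layer {name!r}: crs_kind {layer.crs_kind} != {ref.crs_kind}")
    return report


def ensure_aligned(stack: LayerStack) -> None:
    problems = check_alignment(stack)
    if problems:
        raise AlignmentError("; ".join(problems))


def suitability_map(
    stack: LayerStack,
    profile: CropProfile,
    excluded: Sequence[str] | set[str] = (),
) -> GridLayer:
    """Per-pixel minimum-of-memberships suitability over aligned criterion layers.

    Nodata in any used layer propagates to nodata in the output.
    """
    ensure_aligned(stack)
    excluded = set(excluded)
    used = [c for c in profile.criteria if c.name not in excluded]
    if not used:
        raise InputError("all criteria excluded; nothing to evaluate")
    missing = [c.name for c in used if c.name not in stack]
    if missing:
        raise InputError(f"stack is missing criterion layer(s): {missing}")

    ref = stack[used[0].name]
    invalid = np.zeros(ref.shape, dtype=bool)
    for crit in used:
        invalid |= stack[crit.name].mask

    scores = np.full(ref.shape, np.inf)
    valid = ~invalid
    for crit in used:
        vals = stack[crit.name].values[valid]
        scores[valid] = np.minimum(scores[valid], membership(vals, crit.set))

    out = np.full(ref.shape, NODATA)
    out[valid] = scores[valid]
    return GridLayer(
        values=out,
        transform=ref.transform,
        crs_kind=ref.crs_kind,
        nodata=NODATA,
        criterion="suitability",
        units="score",
    )


def cell_areas(layer: GridLayer) -> np.ndarray:
    """Per-cell areas in km².

    Projected grids (cell sizes in metres) have constant cell area.  Geographic
    grids (cell sizes in degrees) use the spherical band formula per row,
    ``R² · Δλ · |sin φ_top − sin φ_bottom|``, which sums exactly to the sphere.
    """
    nrows, ncols = layer.shape
    t = layer.transform
    if layer.crs_kind == PROJECTED:
        return np.full((nrows, ncols), abs(t.dx * t.dy) / 1e6)
    edges = np.clip(t.row_edges(nrows), -90.0, 90.0)
    sin_edges = np.sin(np.radians(edges))
    band = EARTH_RADIUS_KM**2 * math.radians(t.dx) * np.abs(sin_edges[:-1] - sin_edges[1:])
    return np.repeat(band[:, None], ncols, axis=1)


def _geokey_directory(crs_kind: str) -> tuple[int, ...]:
    # Header (version, revision, minor, key count) then (key, loc, count, value).
    model = 2 if crs_kind == GEOGRAPHIC else 1
    keys = [(1024, 0, 1, model), (1025, 0, 1, 1)]  # model type; pixel-is-area
    if crs_kind == GEOGRAPHIC:
        keys.append((2048, 0, 1, 4326))
    else:
        keys.append((3072, 0, 1, 32767))  # user-defined projected CS
    flat: list[int] = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def write_map(layer: GridLayer, path: str | Path) -> None:
    """Write a layer as a single-band float64 GeoTIFF with nodata and metadata tags."""
    t = layer.transform
    meta_items = []
    if layer.criterion:
        meta_items.append(f'<Item name="criterion">{layer.criterion}</Item>')
    if layer.units:
        meta_items.append(f'<Item name="units">{layer.units}</Item>')
    gkd = _geokey_directory(layer.crs_kind)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_TAG_GEO_KEYS, "H", len(gkd), gkd),
        (_TAG_GDAL_NODATA, "s", 0, str(layer.nodata)),
    ]
    if meta_items:
        xml = "<GDALMetadata>" + "".join(meta_items) + "</GDALMetadata>"
        extratags.append((_TAG_GDAL_METADATA, "s", 0, xml))
    values = layer.values.astype(np.float64, copy=True)
    values[np.isnan(values)] = layer.nodata
    tifffile.imwrite(str(path), values, extratags=extratags)


def read_map(path: str | Path) -> GridLayer:
    """Read a single-band GeoTIFF written by :func:`write_map` (or compatible)."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            tags = page.tags
            values = page.asarray()
            tag_values = {
                code: (tags[code].value if code in tags else None)
                for code in (
                    _TAG_PIXEL_SCALE,
                    _TAG_TIEPOINT,
                    _TAG_GEO_KEYS,
                    _TAG_GDAL_NODATA,
                    _TAG_GDAL_METADATA,
                )
            }
    except (OSError, tifffile.TiffFileError) as exc:
        raise RasterIOError(f"cannot read raster {path}: {exc}") from exc

    scale = tag_values[_TAG_PIXEL_SCALE]
    tiepoint = tag_values[_TAG_TIEPOINT]
    geokeys = tag_values[_TAG_GEO_KEYS]
    if scale is None or tiepoint is None:
        raise RasterIOError(f"raster {path} lacks georeferencing tags")
    if geokeys is None:
        raise RasterIOError(f"raster {path} lacks a CRS (GeoKey directory)")

    dx, dy = float(scale[0]), float(scale[1])
    x_origin = float(tiepoint[3]) - float(tiepoint[0]) * dx
    y_origin = float(tiepoint[4]) + float(tiepoint[1]) * dy

    gk = tuple(int(v) for v in geokeys)
    crs_kind = PROJECTED
    for i in range(4, len(gk) - 3, 4):
        if gk[i] == 1024:
            crs_kind = GEOGRAPHIC if gk[i + 3] == 2 else PROJECTED

    nodata = float(tag_values[_TAG_GDAL_NODATA]) if tag_values[_TAG_GDAL_NODATA] is not None else NODATA

    criterion, units = None, ""
    if tag_values[_TAG_GDAL_METADATA] is not None:
        meta_xml = str(tag_values[_TAG_GDAL_METADATA])
        for name, val in re.findall(r'<Item name="([^"]+)">([^<]*)</Item>', meta_xml):
            if name == "criterion":
                criterion = val
            elif name == "units":
                units = val

    if values.ndim != 2:
        raise RasterIOError(f"raster {path} is not single-band")
    return GridLayer(
        values=np.asarray(values, dtype=float),
        transform=GridTransform(x_origin, y_origin, dx, dy),
        crs_kind=crs_kind,
        nodata=nodata,
        criterion=criterion,
        units=units,
    )


def read_stack(paths: Mapping[str, str | Path]) -> LayerStack:
    """Read several criterion rasters into a stack (alignment is not enforced here)."""
    return LayerStack({name: read_map(p) for name, p in paths.items()})
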