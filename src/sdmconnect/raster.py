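"""Raster containers, grid I/O and derived terrain/landscape layers.

The whole pipeline works on projected, equal-area grids in meters.  A
:class:`RasterGrid` is a plain 2-D array plus the usual lower-left-corner
georeferencing header; row 0 is the northernmost row.  Areas are always
computed from cell counts, so geographic (degree) coordinate systems are
rejected rather than silently reprojected.

Supported on-disk formats are the ESRI ASCII grid (``.asc``) and
single-band GeoTIFF (via :mod:`tifffile` and the standard GeoTIFF
ModelPixelScale / ModelTiepoint tags).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RasterGrid",
    "RasterStack",
    "NodeRaster",
    "RasterParseError",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "distance_to_features",
    "hillshade",
    "hillshade_annual",
    "solar_noon_positions",
    "fragmentation_index",
    "zonal_area",
]

DEFAULT_NODATA = -9999.0


class RasterParseError(ValueError):
    """Raised when a raster file cannot be parsed."""


class AlignmentError(ValueError):
    """Raised when two grids that must share a georeference do not."""


@dataclass
class RasterGrid:
    """A single georeferenced raster layer.

    Attributes
    ----------
    values:
        2-D float array, shape ``(n_rows, n_cols)``; row 0 is north.
    x_min, y_min:
        Coordinates of the lower-left corner of the grid, in meters
        (projected equal-area CRS assumed).
    cell_size:
        Cell edge length in meters, > 0.
    nodata:
        Sentinel for invalid cells (stored verbatim in ``values``).
    name:
        Layer identifier, used as the key inside a :class:`RasterStack`.
    """

    values: np.ndarray
    x_min: float = 0.0
    y_min: float = 0.0
    cell_size: float = 1000.0
    nodata: float = DEFAULT_NODATA
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.cell_size < 1e-3:
            raise ValueError(
                "cell_size below 1 mm: looks like geographic (degree) "
                "coordinates, which are not supported"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of valid (non-nodata, finite) cells."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell ``(row, col)``."""
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_min + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing map point ``(x, y)`` (half-open cell extents)."""
        col = int(math.floor((x - self.x_min) / self.cell_size))
        row = self.n_rows - 1 - int(math.floor((y - self.y_min) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.x_min, other.x_min, abs_tol=1e-6)
            and math.isclose(self.y_min, other.y_min, abs_tol=1e-6)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
        )

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """A copy of this grid's georeference carrying new values."""
        return replace(
            self, values=np.asarray(values, dtype=float), name=name or self.name
        )


@dataclass
class RasterStack:
    """An ordered, aligned collection of named layers sharing one mask."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.aligned_with(grids[0]):
                raise AlignmentError(f"layer {g.name!r} is not aligned with the stack")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        """Conjunction of per-layer validity."""
        m = np.ones(self.template.values.shape, dtype=bool)
        for g in self.layers.values():
            m &= g.mask
        return m

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    def add(self, grid: RasterGrid) -> None:
        if self.layers and not grid.aligned_with(self.template):
            raise AlignmentError(f"layer {grid.name!r} is not aligned with the stack")
        self.layers[grid.name] = grid

    def subset(self, names: Iterable[str]) -> "RasterStack":
        return RasterStack({n: self.layers[n] for n in names})

    def env_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of layer values under the mask."""
        m = self.mask if mask is None else mask
        return np.column_stack([self.layers[n].values[m] for n in self.names])

    def extract(self, xs: Sequence[float], ys: Sequence[float]) -> np.ndarray:
        """Environment matrix at map points (one row per point)."""
        t = self.template
        out = np.empty((len(xs), len(self.layers)))
        for i, (x, y) in enumerate(zip(xs, ys)):
            r, c = t.cell_index(x, y)
            out[i] = [self.layers[n].values[r, c] for n in self.names]
        return out


@dataclass
class NodeRaster:
    """Integer-labeled focal-node regions (0 = background).

    Node regions need not be contiguous: two physically separate reserves
    administered as one unit may share a label and are then treated as a
    single terminal by the connectivity solver.
    """

    labels: np.ndarray
    node_names: dict[int, str] = field(default_factory=dict)
    x_min: float = 0.0
    y_min: float = 0.0
    cell_size: float = 1000.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels)) - {0}
        if not self.node_names:
            self.node_names = {int(k): f"node_{k}" for k in sorted(present)}
        missing = [k for k in self.node_names if k not in present]
        if missing:
            raise ValueError(f"labels {missing} named but absent from the raster")

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.node_names)

    def as_grid(self) -> RasterGrid:
        return RasterGrid(
            self.labels.astype(float),
            x_min=self.x_min,
            y_min=self.y_min,
            cell_size=self.cell_size,
            nodata=-1,
            name="nodes",
        )

    @classmethod
    def from_grid(cls, grid: RasterGrid, node_names: dict[int, str] | None = None) -> "NodeRaster":
        labels = np.where(grid.mask, grid.values, 0).astype(int)
        return cls(
            labels,
            node_names or {},
            x_min=grid.x_min,
            y_min=grid.y_min,
            cell_size=grid.cell_size,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_asc(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        n_header = 0
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
            if not m or m.group(1).lower() not in _ASC_HEADER_KEYS + ("nodata_value",):
                fh.seek(pos)
                break
            key = m.group(1).lower()
            try:
                header[key] = float(m.group(2))
            except ValueError as exc:
                raise RasterParseError(f"bad value for header key {key!r}: {m.group(2)!r}") from exc
            n_header += 1
        for key in _ASC_HEADER_KEYS:
            if key not in header:
                raise RasterParseError(f"missing required header key {key!r}")
        rows: list[list[float]] = []
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise RasterParseError(
                    f"non-numeric token in data row {i + 1} of {path.name}"
                ) from exc
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array(rows, dtype=float) if rows else np.empty((0, 0))
    if values.shape != (nrows, ncols):
        raise RasterParseError(
            f"data shape {values.shape} does not match header "
            f"nrows={nrows} ncols={ncols}"
        )
    return RasterGrid(
        values,
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        name=path.stem,
    )


def _format_value(v: float) -> str:
    """6-significant-digit text convention; integers stay integral."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return f"{v:.6g}"


def _write_asc(grid: RasterGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {_format_value(grid.x_min)}\n")
        fh.write(f"yllcorner {_format_value(grid.y_min)}\n")
        fh.write(f"cellsize {_format_value(grid.cell_size)}\n")
        fh.write(f"NODATA_value {_format_value(grid.nodata)}\n")
        for row in grid.values:
            fh.write(" ".join(_format_value(v) for v in row) + "\n")


def _read_gtiff(path: Path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise RasterParseError("only single-band GeoTIFFs are supported")
        tags = {t.name: t.value for t in page.tags.values()}
    scale = tags.get("ModelPixelScaleTag")
    tie = tags.get("ModelTiepointTag")
    if scale is None or tie is None:
        raise RasterParseError("GeoTIFF lacks ModelPixelScale/ModelTiepoint tags")
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise RasterParseError("non-square pixels are not supported")
    # tiepoint maps raster (0, 0) upper-left corner to map (x, y)
    x_ul, y_ul = float(tie[3]), float(tie[4])
    nodata = float(tags.get("GDAL_NODATA", DEFAULT_NODATA))
    n_rows = values.shape[0]
    return RasterGrid(
        values,
        x_min=x_ul,
        y_min=y_ul - n_rows * sy,
        cell_size=sx,
        nodata=nodata,
        name=path.stem,
    )


def _write_gtiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    y_ul = grid.y_min + grid.n_rows * grid.cell_size
    extratags = [
        (33550, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.x_min, y_ul, 0.0)),  # ModelTiepoint
        (42113, "s", 0, _format_value(grid.nodata)),  # GDAL_NODATA
    ]
    tifffile.imwrite(str(path), grid.values, extratags=extratags)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return "asc"
    if suffix in (".tif", ".tiff", ".gtiff"):
        return "gtiff"
    raise ValueError(f"cannot infer raster format from {path.name!r}")


def read_raster(path: str | Path, format: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid or single-band GeoTIFF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "asc":
        return _read_asc(path)
    if fmt == "gtiff":
        return _read_gtiff(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_raster(grid: RasterGrid, path: str | Path, format: str | None = None) -> Path:
    """Write a grid; ``.asc`` uses a 6-significant-digit text convention."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "asc":
        _write_asc(grid, path)
    elif fmt == "gtiff":
        _write_gtiff(grid, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_stack(paths: Iterable[str | Path]) -> RasterStack:
    stack = RasterStack()
    for p in paths:
        stack.add(read_raster(p))
    return stack


# ---------------------------------------------------------------------------
# Derived layers
# ---------------------------------------------------------------------------


def distance_to_features(features: RasterGrid) -> RasterGrid:
    """Euclidean distance (meters) from each cell center to the nearest
    feature cell center; feature cells score 0."""
    feat = features.mask & (features.values != 0)
    if not feat.any():
        raise ValueError("no feature cells: distance surface undefined")
    dist = ndimage.distance_transform_edt(~feat) * features.cell_size
    return features.with_values(dist, name=f"dist_{features.name}")


def _horn_slope_aspect(dem: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Slope and aspect (radians) by Horn's 3x3 weighted differences.

    Aspect is measured clockwise from north (geographic convention).
    Edge cells use replicated borders.
    """
    z = np.pad(dem, 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell_size)
    slope = np.arctan(np.hypot(dzdx, dzdy))
    # downslope (facing) direction, clockwise from north
    aspect = np.arctan2(-dzdx, dzdy) % (2 * np.pi)
    return slope, aspect


def hillshade(
    dem: RasterGrid, azimuth_deg: float, altitude_deg: float
) -> RasterGrid:
    """Standard analytical hillshade for one sun position, in [0, 255]."""
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("hillshade needs at least a 3x3 grid")
    slope, aspect = _horn_slope_aspect(dem.values, dem.cell_size)
    zenith = np.deg2rad(90.0 - altitude_deg)
    az = np.deg2rad(azimuth_deg)
    shade = 255.0 * np.maximum(
        0.0,
        np.cos(zenith) * np.cos(slope)
        + np.sin(zenith) * np.sin(slope) * np.cos(az - aspect),
    )
    out = np.where(dem.mask, shade, dem.nodata)
    return dem.with_values(out, name="hillshade")


def solar_noon_positions(latitude_deg: float) -> list[tuple[float, float]]:
    """Twelve monthly solar-noon (azimuth, altitude) pairs for a latitude.

    Solar declination is taken at the middle of each month from the
    standard cosine approximation; at solar noon the sun sits due south
    (northern hemisphere) at altitude 90 - |lat - declination|.
    """
    positions = []
    for month in range(12):
        day = 30.4 * month + 15  # mid-month day-of-year
        decl = -23.44 * math.cos(math.radians(360.0 / 365.0 * (day + 10)))
        alt = 90.0 - abs(latitude_deg - decl)
        alt = max(alt, 0.0)
        azimuth = 180.0 if latitude_deg >= decl else 0.0
        positions.append((azimuth, alt))
    return positions


def hillshade_annual(
    dem: RasterGrid,
    sun_positions: Sequence[tuple[float, float]] | None = None,
    latitude_deg: float = 28.0,
) -> RasterGrid:
    """Mean hillshade over a set of sun positions (default: 12 monthly
    solar-noon positions at ``latitude_deg``).

    The result summarises the average illumination each cell receives
    over a year; shadier cells retain more moisture.
    """
    if sun_positions is None:
        sun_positions = solar_noon_positions(latitude_deg)
    if not sun_positions:
        raise ValueError("sun_positions must be non-empty")
    acc = np.zeros_like(dem.values)
    for az, alt in sun_positions:
        acc += hillshade(dem, az, alt).values
    out = np.where(dem.mask, acc / len(sun_positions), dem.nodata)
    return dem.with_values(out, name="hillshade_annual")


def fragmentation_index(landcover: RasterGrid) -> RasterGrid:
    """Per-cell landscape fragmentation in [0, 1] from a categorical map.

    For each 3x3 window, F = (# rook-adjacent cell pairs with differing
    classes) / (# rook-adjacent pairs inside the window) — 12 pairs in
    the interior, fewer at the grid edge.  Uniform windows give 0, a
    two-class checkerboard gives 1.  Pairs touching nodata are dropped
    from numerator and denominator; an all-nodata window yields nodata.
    """
    vals = landcover.values
    valid = landcover.mask
    n, m = vals.shape
    # horizontal pair (i, j) spans cells (i, j)-(i, j+1); vertical pair
    # (i, j) spans (i, j)-(i+1, j).  A pair lies inside the 3x3 window of
    # cell (r, c) iff its rows fit r-1..r+1 and its cols fit c-1..c+1.
    h_valid = np.zeros((n, m))
    h_diff = np.zeros((n, m))
    hv = valid[:, :-1] & valid[:, 1:]
    h_valid[:, : m - 1] = hv
    h_diff[:, : m - 1] = hv & (vals[:, :-1] != vals[:, 1:])
    v_valid = np.zeros((n, m))
    v_diff = np.zeros((n, m))
    vv = valid[:-1, :] & valid[1:, :]
    v_valid[: n - 1, :] = vv
    v_diff[: n - 1, :] = vv & (vals[:-1, :] != vals[1:, :])

    # a (3, 2) correlate kernel sums offsets rows -1..+1, cols -1..0,
    # exactly the horizontal pairs whose two cells fit the window
    kh = np.ones((3, 2))
    kv = np.ones((2, 3))
    diff_count = ndimage.correlate(h_diff, kh, mode="constant") + ndimage.correlate(
        v_diff, kv, mode="constant"
    )
    pair_count = ndimage.correlate(h_valid, kh, mode="constant") + ndimage.correlate(
        v_valid, kv, mode="constant"
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frag = np.where(pair_count > 0, diff_count / np.maximum(pair_count, 1), landcover.nodata)
    frag = np.where(valid, frag, landcover.nodata)
    return landcover.with_values(frag, name="fragmentation")


def zonal_area(binary: RasterGrid, nodes: NodeRaster):
    """Suitable-area bookkeeping: total, inside and outside focal nodes.

    Returns a DataFrame with one row: ``area_km2`` (all suitable cells),
    ``inside_km2`` (suitable cells under any node label) and
    ``outside_km2``; ``inside + outside == area`` exactly.
    """
    import pandas as pd

    if binary.values.shape != nodes.labels.shape:
        raise AlignmentError("binary map and node raster are not aligned")
    if not (
        math.isclose(binary.x_min, nodes.x_min, abs_tol=1e-6)
        and math.isclose(binary.y_min, nodes.y_min, abs_tol=1e-6)
        and math.isclose(binary.cell_size, nodes.cell_size, rel_tol=1e-9)
    ):
        raise AlignmentError("binary map and node raster are not aligned")
    suit = binary.mask & (binary.values == 1)
    km2 = binary.cell_size**2 / 1e6
    total = int(suit.sum())
    inside = int((suit & (nodes.labels > 0)).sum())
    return pd.DataFrame(
        [
            {
                "area_km2": total * km2,
                "inside_km2": inside * km2,
                "outside_km2": (total - inside) * km2,
            }
        ]
    )
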