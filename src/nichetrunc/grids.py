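"""Grid geometry, co-registered raster stacks, block aggregation and
topographic derivatives.

All layers live on one projected equal-area grid (the analyses assume an
Albers-type projection), so every cell covers exactly ``cell_size ** 2``
square kilometres and areas are obtained by counting cells.  Internally a
layer is a 2-D ``float64`` array with ``numpy.nan`` as the missing-data
value; the sentinel in :class:`GridGeometry` is only used when reading or
writing files.  Row 0 is the northernmost row (raster convention); the
geometry origin is the lower-left corner of the grid in projected km.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GridGeometry",
    "GridStack",
    "aggregate_to_grid",
    "derive_topography",
    "compute_pairwise_correlations",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "load_stack",
    "write_stack",
    "CLIMATE_VARIABLES",
    "TEMPERATURE_VARIABLES",
    "PRECIPITATION_VARIABLES",
    "ENVELOPE_VARIABLES",
]

#: the eight candidate bioclimatic variables
CLIMATE_VARIABLES = (
    "AMT", "MTWQ", "MTCQ", "MinTCM", "PANN", "PWetQ", "PDryQ", "PColdQ",
)
TEMPERATURE_VARIABLES = ("AMT", "MTWQ", "MTCQ", "MinTCM")
PRECIPITATION_VARIABLES = ("PANN", "PWetQ", "PDryQ", "PColdQ")
#: the five variables used by the rectilinear envelope model
ENVELOPE_VARIABLES = ("PANN", "PDryQ", "MinTCM", "MTCQ", "MTWQ")

# value ranges enforced on known layers (inclusive), nodata always allowed
_LAYER_RANGES = {"TREECOV": (0.0, 100.0), "HII": (0.0, 64.0), "PA": (0.0, 1.0)}


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a projected equal-area grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; row 0 is the top (northernmost) row.
    cell_size:
        Cell edge length in km; cell area is ``cell_size ** 2`` km².
    origin_x, origin_y:
        Projected coordinates (km) of the lower-left grid corner.
    nodata:
        Sentinel used in files; in memory nodata is ``nan``.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Area of one cell in km²."""
        return self.cell_size**2

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) of every cell centre as two (n_rows, n_cols) arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each projected point."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((y - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class GridStack:
    """A set of co-registered single-band layers keyed by variable name.

    Layers must share one :class:`GridGeometry`; mismatched shapes are
    rejected rather than resampled, so alignment errors surface early.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in list(self.layers):
            self.layers[name] = self._validate(name, self.layers[name])

    def _validate(self, name: str, layer: np.ndarray) -> np.ndarray:
        arr = np.asarray(layer, dtype=float)
        if arr.shape != self.geometry.shape:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, grid is {self.geometry.shape}"
            )
        if name in _LAYER_RANGES:
            lo, hi = _LAYER_RANGES[name]
            vals = arr[np.isfinite(arr)]
            if vals.size and (vals.min() < lo or vals.max() > hi):
                raise ValueError(f"layer {name!r} has values outside [{lo}, {hi}]")
        return arr

    def add(self, name: str, layer: np.ndarray) -> None:
        self.layers[name] = self._validate(name, layer)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def variables(self) -> list[str]:
        return list(self.layers)

    def valid_mask(self, variables=None) -> np.ndarray:
        """Cells valid (non-nodata) in every requested layer."""
        variables = list(self.layers) if variables is None else list(variables)
        if not variables:
            raise ValueError("no variables given")
        mask = np.ones(self.geometry.shape, dtype=bool)
        for v in variables:
            mask &= np.isfinite(self.layers[v])
        return mask

    def values_at(self, rows, cols, variables=None) -> dict[str, np.ndarray]:
        variables = list(self.layers) if variables is None else list(variables)
        return {v: self.layers[v][rows, cols] for v in variables}


def aggregate_to_grid(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-aggregate a fine layer to a coarser resolution by block means.

    Each coarse cell is the mean of its ``factor x factor`` block of fine
    cells, ignoring nodata; an all-nodata block becomes nodata.  Dimensions
    not divisible by ``factor`` are padded with nodata.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    arr = np.asarray(fine, dtype=float)
    if factor == 1:
        return arr.copy()
    nr, nc = arr.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), constant_values=np.nan)
    blocks = arr.reshape(arr.shape[0] // factor, factor, arr.shape[1] // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan blocks
        return np.nanmean(blocks, axis=(1, 3))


def _shifted_windows(arr: np.ndarray) -> np.ndarray:
    """Stack of the 9 edge-replicated 3x3 neighbour views, nodata neighbours
    replaced by the centre value (the usual DEM convention)."""
    padded = np.pad(arr, 1, mode="edge")
    stack = np.empty((3, 3) + arr.shape, dtype=float)
    for dr in range(3):
        for dc in range(3):
            stack[dr, dc] = padded[dr : dr + arr.shape[0], dc : dc + arr.shape[1]]
    centre = stack[1, 1]
    missing = ~np.isfinite(stack)
    stack = np.where(missing, np.broadcast_to(centre, stack.shape), stack)
    return stack


def _horn_slope(arr: np.ndarray, cell_m: float) -> np.ndarray:
    """Horn 3x3 slope in degrees on a projected grid with cell size in metres."""
    w = _shifted_windows(arr)
    # rows increase southwards: w[0] is the northern neighbour row
    dz_dx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2]) - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (
        8 * cell_m
    )
    dz_dy = ((w[0, 0] + 2 * w[0, 1] + w[0, 2]) - (w[2, 0] + 2 * w[2, 1] + w[2, 2])) / (
        8 * cell_m
    )
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    slope[~np.isfinite(arr)] = np.nan
    return slope


def derive_topography(elev: np.ndarray, geometry: GridGeometry) -> dict[str, np.ndarray]:
    """Slope, windowed standard deviation and roughness from elevation.

    ``Slope`` is the Horn 3x3 gradient in degrees, ``STD`` the standard
    deviation of elevation in the 3x3 window, and ``TR`` (topographic
    roughness) the slope of the slope layer.  Elevation is in metres; the
    grid cell size (km) is converted internally.  Edge cells use the
    available neighbourhood via edge replication.
    """
    arr = np.asarray(elev, dtype=float)
    if np.isfinite(arr).sum() < 9:
        raise ValueError("need at least a 3x3 block of valid elevation cells")
    cell_m = geometry.cell_size * 1000.0
    slope = _horn_slope(arr, cell_m)
    w = _shifted_windows(arr).reshape(9, *arr.shape)
    std = w.std(axis=0)
    std[~np.isfinite(arr)] = np.nan
    tr = _horn_slope(slope, cell_m)
    return {"Slope": slope, "STD": std, "TR": tr}


def compute_pairwise_correlations(stack: GridStack, variables) -> "pandas.DataFrame":
    """Pairwise Pearson correlations over cells valid in both layers.

    A zero-variance layer yields undefined correlations, reported as NaN.
    The diagonal is exactly 1.
    """
    import pandas as pd

    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    flat = {v: stack[v].ravel() for v in variables}
    n = len(variables)
    r = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = flat[variables[i]], flat[variables[j]]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 jointly valid cells for {variables[i]}/{variables[j]}"
                )
            aa, bb = a[ok], b[ok]
            if aa.std() == 0 or bb.std() == 0:
                continue  # undefined, left as NaN
            r[i, j] = r[j, i] = np.corrcoef(aa, bb)[0, 1]
    return pd.DataFrame(r, index=variables, columns=variables)


# ---------------------------------------------------------------------------
# file formats: ESRI ASCII grid and (minimally georeferenced) GeoTIFF

def write_ascii_grid(path, layer: np.ndarray, geometry: GridGeometry) -> None:
    arr = np.asarray(layer, dtype=float)
    out = np.where(np.isfinite(arr), arr, geometry.nodata)
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.origin_x!r}\n"
        f"yllcorner {geometry.origin_y!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {geometry.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    with open(path) as fh:
        head = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            head[parts[0].lower()] = float(parts[1])
        arr = np.loadtxt(fh, ndmin=2)
    geom = GridGeometry(
        n_rows=int(head["nrows"]),
        n_cols=int(head["ncols"]),
        cell_size=head["cellsize"],
        origin_x=head.get("xllcorner", 0.0),
        origin_y=head.get("yllcorner", 0.0),
        nodata=head.get("nodata_value", -9999.0),
    )
    arr[arr == geom.nodata] = np.nan
    return arr, geom


def write_geotiff(path, layer: np.ndarray, geometry: GridGeometry) -> None:
    """Single-band float GeoTIFF with pixel-scale / tiepoint georeferencing."""
    arr = np.asarray(layer, dtype=np.float32)
    top = geometry.origin_y + geometry.n_rows * geometry.cell_size
    scale = (geometry.cell_size, geometry.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, geometry.origin_x, top, 0.0)
    tifffile.imwrite(
        path,
        arr,
        extratags=[
            (33550, "d", 3, scale),        # ModelPixelScaleTag
            (33922, "d", 6, tiepoint),     # ModelTiepointTag
            (42113, "s", 0, str(geometry.nodata)),  # GDAL_NODATA
        ],
    )


def read_geotiff(path) -> tuple[np.ndarray, GridGeometry]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        tags = page.tags
        scale = tags[33550].value
        tiepoint = tags[33922].value
        nodata = float(tags[42113].value) if 42113 in tags else -9999.0
    cell = float(scale[0])
    n_rows, n_cols = arr.shape
    origin_x = float(tiepoint[3])
    origin_y = float(tiepoint[4]) - n_rows * cell
    arr[arr == nodata] = np.nan
    return arr, GridGeometry(n_rows, n_cols, cell, origin_x, origin_y, nodata)


def _read_layer(path: Path) -> tuple[np.ndarray, GridGeometry]:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_geotiff(path)
    return read_ascii_grid(path)


def load_stack(manifest_path) -> GridStack:
    """Load a stack from a plain-text manifest of ``name = path`` lines.

    Relative paths are resolved against the manifest's directory; all layers
    must share one grid geometry.
    """
    manifest_path = Path(manifest_path)
    entries: list[tuple[str, Path]] = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            name, _, p = (s.strip() for s in line.partition("="))
        else:
            p = line
            name = Path(p).stem
        entries.append((name, (manifest_path.parent / p).resolve()))
    if not entries:
        raise ValueError(f"manifest {manifest_path} lists no layers")
    stack = None
    for name, p in entries:
        arr, geom = _read_layer(p)
        if stack is None:
            stack = GridStack(geom)
        elif geom != stack.geometry:
            raise ValueError(f"layer {name!r} geometry differs from the stack's")
        stack.add(name, arr)
    return stack


def write_stack(stack: GridStack, out_dir, fmt: str = "asc") -> Path:
    """Write every layer plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, layer in stack.layers.items():
        fname = f"{name}.{fmt}"
        if fmt == "asc":
            write_ascii_grid(out_dir / fname, layer, stack.geometry)
        else:
            write_geotiff(out_dir / fname, layer, stack.geometry)
        lines.append(f"{name} = {fname}")
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
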