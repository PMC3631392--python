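"""Raster and vector I/O on a single geographic lattice.

Everything downstream of this module works on co-registered grids in
geographic degrees: one origin, one square cell size, one shape.  Rasters
are exchanged as ESRI ASCII grids or single-band GeoTIFFs, occurrences as
``species,lon,lat`` CSV, and range polygons as GeoJSON.  No reprojection or
resampling is performed anywhere: inputs must already share the lattice
(:func:`check_coregistered` enforces this with a 1e-9 degree tolerance).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

__all__ = [
    "Grid",
    "ClimateStack",
    "OccurrenceSet",
    "PolygonSet",
    "GridParseError",
    "CoregistrationError",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "resolve_occurrences",
    "check_coregistered",
    "read_polygons",
    "write_polygons",
]

GEOM_TOL = 1e-9  # degrees; lattices closer than this are "the same"


class GridParseError(ValueError):
    """A raster file could not be parsed under the requested dialect."""


class CoregistrationError(ValueError):
    """Two grids that must share a lattice do not."""


@dataclass
class Grid:
    """A single georeferenced raster layer.

    ``values`` is stored in file order: row 0 is the northernmost row.
    ``(x_origin, y_origin)`` is the lower-left corner of the extent and
    ``mask`` is True on nodata cells.  Cell (r, c) covers the half-open
    box ``[x0 + c*cs, x0 + (c+1)*cs) x [y0 + (nrows-1-r)*cs, ...)``.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite value on an unmasked cell")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def geometry(self) -> tuple[int, int, float, float, float]:
        return (self.n_rows, self.n_cols, self.x_origin, self.y_origin, self.cell_size)

    def same_geometry(self, other: "Grid", tol: float = GEOM_TOL) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New grid on this lattice with different values."""
        return Grid(np.array(values, dtype=float), self.x_origin, self.y_origin,
                    self.cell_size, None if mask is None else np.array(mask, dtype=bool))

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the half-open cell containing a point, or None if outside."""
        col = int(np.floor((lon - self.x_origin) / self.cell_size))
        row_s = int(np.floor((lat - self.y_origin) / self.cell_size))  # from south
        if not (0 <= col < self.n_cols and 0 <= row_s < self.n_rows):
            return None
        return self.n_rows - 1 - row_s, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of every cell centre, shaped like ``values``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.x_origin + (cols + 0.5) * self.cell_size
        lat = self.y_origin + (self.n_rows - rows - 0.5) * self.cell_size
        return np.broadcast_to(lon, (self.n_rows, self.n_cols)).copy(), \
            np.broadcast_to(lat[:, None], (self.n_rows, self.n_cols)).copy()

    def row_latitudes(self) -> np.ndarray:
        """Latitude of each row centre (north to south)."""
        rows = np.arange(self.n_rows)
        return self.y_origin + (self.n_rows - rows - 0.5) * self.cell_size


class ClimateStack:
    """Named, co-registered covariate layers sharing one lattice."""

    def __init__(self, layers: dict[str, Grid]):
        if not layers:
            raise ValueError("ClimateStack needs at least one layer")
        if len(set(layers)) != len(layers):
            raise ValueError("duplicate layer names")
        check_coregistered(list(layers.values()))
        self.layers = dict(layers)

    def __getitem__(self, name: str) -> Grid:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"covariate {name!r} not in stack "
                           f"(have {sorted(self.layers)})") from None

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self):
        return iter(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    def combined_mask(self) -> np.ndarray:
        """True wherever any layer is nodata."""
        out = np.zeros(self.template.values.shape, dtype=bool)
        for g in self.layers.values():
            out |= g.mask
        return out

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        return ClimateStack({n: self[n] for n in names})

    def with_layer(self, name: str, grid: Grid) -> "ClimateStack":
        layers = dict(self.layers)
        layers[name] = grid
        return ClimateStack(layers)


@dataclass
class OccurrenceSet:
    """One species' presence records resolved onto a grid.

    ``records`` keeps every accepted raw coordinate; ``cell_ids`` the cell of
    each record (duplicates allowed); ``presence_cells`` the de-duplicated
    cells actually used for model fitting; ``rejected`` the (lon, lat, reason)
    triples that did not resolve.
    """

    species: str
    records: list[tuple[float, float]]
    cell_ids: list[tuple[int, int]]
    presence_cells: list[tuple[int, int]]
    rejected: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_cells(self) -> int:
        return len(self.presence_cells)

    @property
    def has_duplicate_cells(self) -> bool:
        return len(self.presence_cells) < len(self.cell_ids)


@dataclass
class PolygonSet:
    """Extent-of-occurrence polygons for one species (lon/lat degrees)."""

    species: str
    geoms: list[Polygon]

    def __post_init__(self) -> None:
        if not self.geoms:
            raise ValueError("PolygonSet needs at least one polygon")
        for g in self.geoms:
            if g.is_empty or g.area == 0:
                raise ValueError("zero-area polygon")

    def union(self) -> Polygon | MultiPolygon:
        out = self.geoms[0]
        for g in self.geoms[1:]:
            out = out.union(g)
        return out


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

_ASCII_NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_esri_ascii(path: Path) -> Grid:
    with open(path) as fh:
        tokens: dict[str, float] = {}
        lines = fh.readlines()
    idx = 0
    nodata = _ASCII_NODATA
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                tokens[key] = float(parts[1])
            except ValueError as exc:
                raise GridParseError(f"{path}: bad header value on line {idx + 1}: {parts[1]!r}") from exc
            idx += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in tokens:
            raise GridParseError(f"{path}: missing header token {key!r}")
    nodata = tokens.get("nodata_value", _ASCII_NODATA)
    n_rows, n_cols = int(tokens["nrows"]), int(tokens["ncols"])
    try:
        data = np.loadtxt(lines[idx:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise GridParseError(f"{path}: bad data block: {exc}") from exc
    flat = data.ravel()
    if flat.size != n_rows * n_cols:
        raise GridParseError(
            f"{path}: data has {flat.size} cells, header says {n_rows}x{n_cols}")
    values = flat.reshape(n_rows, n_cols)
    mask = np.isclose(values, nodata) | ~np.isfinite(values)
    values = np.where(mask, np.nan, values)
    return Grid(values, tokens["xllcorner"], tokens["yllcorner"], tokens["cellsize"], mask)


def _write_esri_ascii(grid: Grid, path: Path) -> None:
    out = np.where(grid.mask, _ASCII_NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {_ASCII_NODATA:g}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# GeoTIFF tag ids used for plain lat/lon georeferencing
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else None
            tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else None
            nodata_tag = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else None
    except Exception as exc:  # malformed container
        raise GridParseError(f"{path}: not a readable TIFF: {exc}") from exc
    if values.ndim != 2:
        raise GridParseError(f"{path}: expected a single-band raster, got shape {values.shape}")
    if scale is None or tie is None:
        raise GridParseError(f"{path}: missing georeferencing tags (ModelPixelScale/ModelTiepoint)")
    sx, sy = scale[:2]
    if abs(sx - sy) > GEOM_TOL:
        raise GridParseError(f"{path}: non-square cells ({sx} x {sy})")
    x_top_left, y_top_left = tie[3], tie[4]
    n_rows = values.shape[0]
    mask = ~np.isfinite(values)
    if nodata_tag is not None:
        nodata = float(str(nodata_tag).strip("\x00"))
        mask |= np.isclose(values, nodata)
    values = np.where(mask, np.nan, values)
    return Grid(values, x_top_left, y_top_left - n_rows * sy, sx, mask)


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    out = np.where(grid.mask, _ASCII_NODATA, grid.values)
    y_top = grid.y_origin + grid.n_rows * grid.cell_size
    nodata_ascii = f"{_ASCII_NODATA:g}\x00".encode()
    tifffile.imwrite(
        path,
        out.astype(np.float64),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, y_top, 0.0)),
            (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii),
        ],
    )


def read_raster(path: str | Path, dialect: str | None = None) -> Grid:
    """Read a raster as a :class:`Grid`, masking nodata, never resampling.

    ``dialect`` is ``"esri_ascii"`` or ``"geotiff"``; when omitted it is
    inferred from the file suffix (.asc/.txt vs .tif/.tiff).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if dialect == "esri_ascii":
        return _read_esri_ascii(path)
    if dialect == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster dialect {dialect!r}")


def write_raster(grid: Grid, path: str | Path, dialect: str | None = None) -> Path:
    """Write a :class:`Grid`; the write→read round trip is value-exact."""
    path = Path(path)
    if dialect is None:
        dialect = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if dialect == "esri_ascii":
        _write_esri_ascii(grid, path)
    elif dialect == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a ``species,lon,lat`` CSV into per-species coordinate lists."""
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "lon", "lat"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: occurrence CSV must have columns species,lon,lat")
        for row in reader:
            out.setdefault(row["species"], []).append((float(row["lon"]), float(row["lat"])))
    return out


def write_occurrences(occ: dict[str, list[tuple[float, float]]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "lon", "lat"])
        for species in occ:
            for lon, lat in occ[species]:
                writer.writerow([species, repr(lon), repr(lat)])
    return path


def resolve_occurrences(
    species: str,
    coords: Iterable[tuple[float, float]],
    grid: Grid,
) -> OccurrenceSet:
    """Map raw coordinates to grid cells (half-open cell intervals).

    Records outside the extent or on nodata cells are collected in
    ``rejected`` with a reason; duplicate cells are collapsed (order
    preserving) into ``presence_cells`` while the raw records are kept.
    Raises ``ValueError`` if every record is rejected.
    """
    records: list[tuple[float, float]] = []
    cell_ids: list[tuple[int, int]] = []
    rejected: list[tuple[float, float, str]] = []
    seen: dict[tuple[int, int], None] = {}
    for lon, lat in coords:
        cell = grid.cell_of(lon, lat)
        if cell is None:
            rejected.append((lon, lat, "out_of_extent"))
            continue
        if grid.mask[cell]:
            rejected.append((lon, lat, "nodata_cell"))
            continue
        records.append((lon, lat))
        cell_ids.append(cell)
        seen.setdefault(cell)
    if not records:
        raise ValueError(
            f"{species}: no occurrence records resolved onto the grid "
            f"({len(rejected)} rejected)")
    return OccurrenceSet(species, records, cell_ids, list(seen), rejected)


def check_coregistered(grids: Sequence[Grid], tol: float = GEOM_TOL) -> None:
    """Raise :class:`CoregistrationError` naming the first differing field."""
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    fields = ("n_rows", "n_cols", "x_origin", "y_origin", "cell_size")
    for i, g in enumerate(grids[1:], start=1):
        for name in fields:
            a, b = getattr(ref, name), getattr(g, name)
            if abs(a - b) > (0 if name in ("n_rows", "n_cols") else tol):
                raise CoregistrationError(
                    f"grid {i} differs from grid 0 in {name}: {b!r} vs {a!r}")


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------

def read_polygons(path: str | Path) -> dict[str, PolygonSet]:
    """Read a GeoJSON FeatureCollection of (Multi)Polygons keyed by species."""
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, PolygonSet] = {}
    features = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    for feat in features:
        species = feat.get("properties", {}).get("species", "unknown")
        geom = shape(feat["geometry"])
        polys = list(geom.geoms) if isinstance(geom, MultiPolygon) else [geom]
        if species in out:
            out[species] = PolygonSet(species, out[species].geoms + polys)
        else:
            out[species] = PolygonSet(species, polys)
    return out


def write_polygons(polys: dict[str, PolygonSet], path: str | Path) -> Path:
    path = Path(path)
    features = []
    for species, ps in polys.items():
        geom = MultiPolygon(ps.geoms) if len(ps.geoms) > 1 else ps.geoms[0]
        features.append({
            "type": "Feature",
            "properties": {"species": species},
            "geometry": mapping(geom),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
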