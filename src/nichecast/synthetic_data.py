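"""Seeded synthetic study fixtures: terrain, climate, forest, virtual species.

The generator emulates the data inventory of a tropical-island study of
forest-restricted birds: a smooth digital elevation model spanning
0–2750 m, monthly temperature with an elevational lapse and a southern-
hemisphere seasonal cycle, monthly precipitation with wet/dry seasons and
an east–west moisture gradient, a patchy fine-resolution binary forest map
whose cover is partly (not wholly) predictable from climate, a warmed
future scenario (+2 °C by default, slightly drier), and virtual species
with known Gaussian niches in derived covariates plus a forest-cover
response.  Occurrence records are presence-only draws proportional to true
suitability; extent-of-occurrence polygons are buffered convex hulls of
the records, deliberately larger than the realised niche.

Every operation is a pure function of (seed, parameters); the default
species design reproduces the published occurrence-count table packaged in
``data/bird_records.csv`` (17 species over 18 design rows, counts 1–25).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Polygon, box

from .climate_derive import MonthlyClimate, derive_covariates, forest_percent
from .geo_io import (ClimateStack, Grid, OccurrenceSet, PolygonSet,
                     resolve_occurrences, write_occurrences, write_polygons,
                     write_raster)

__all__ = [
    "NicheParams",
    "SpeciesFixture",
    "StudyFixture",
    "default_design",
    "make_terrain",
    "make_climate",
    "apply_scenario",
    "true_suitability",
    "sample_species",
    "make_eoo",
    "make_study_fixture",
]

# default lattice: a ~0.83 degree window at Madagascar-like latitudes,
# 30 arc-second cells
DEFAULT_SHAPE = (100, 100)
DEFAULT_CELL = 1.0 / 120.0
DEFAULT_ORIGIN = (47.0, -19.6)
ELEV_RANGE = (0.0, 2750.0)


@dataclass
class NicheParams:
    """A virtual species' true response: Gaussian in each named covariate,
    optionally weighted by forest cover ((forest/100)^forest_dependence)."""

    optima: dict[str, float]
    tolerances: dict[str, float]
    forest_dependence: float = 0.0
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.tolerances):
            raise ValueError("optima and tolerances must name the same covariates")
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be positive")
        if not 0 < self.max_suitability <= 1:
            raise ValueError("max_suitability must lie in (0, 1]")
        if self.forest_dependence < 0:
            raise ValueError("forest_dependence must be ≥ 0")


@dataclass
class SpeciesFixture:
    name: str
    record_rows: list[int]            # design row counts (a species may have >1 row)
    niche: NicheParams
    occurrences: OccurrenceSet
    eoo: PolygonSet
    true_suit: Grid

    @property
    def n_records(self) -> int:
        return sum(self.record_rows)

    def is_modeled(self, min_records: int = 6) -> bool:
        """A species enters the analysis iff any single design row reaches
        ``min_records`` records (disjunct single-record populations listed
        as separate rows do not push a species over the cutoff)."""
        return any(r >= min_records for r in self.record_rows)


@dataclass
class StudyFixture:
    """Complete seeded study bundle; all grids co-registered."""

    seed: int
    dem: Grid
    forest_fine: Grid
    forest_pct: Grid
    climate_current: MonthlyClimate
    climate_future: MonthlyClimate
    stack_current: ClimateStack       # nine climate covariates + forest_pct
    stack_future: ClimateStack
    species: list[SpeciesFixture]
    design: pd.DataFrame
    scenario: dict = field(default_factory=dict)

    def species_by_name(self, name: str) -> SpeciesFixture:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def modeled_species(self, min_records: int = 6) -> list[SpeciesFixture]:
        return [sp for sp in self.species if sp.is_modeled(min_records)]

    def excluded_species(self, min_records: int = 6) -> list[SpeciesFixture]:
        return [sp for sp in self.species if not sp.is_modeled(min_records)]

    def save(self, out_dir: str | Path) -> Path:
        """Serialize as ESRI ASCII rasters + CSV + GeoJSON + JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_raster(self.dem, out / "dem.asc")
        write_raster(self.forest_pct, out / "forest_pct.asc")
        write_raster(self.forest_fine, out / "forest_fine.asc")
        for m in range(12):
            write_raster(self.climate_current.temp[m], out / f"temp_{m + 1:02d}.asc")
            write_raster(self.climate_current.precip[m], out / f"precip_{m + 1:02d}.asc")
            write_raster(self.climate_future.temp[m], out / f"temp_future_{m + 1:02d}.asc")
            write_raster(self.climate_future.precip[m], out / f"precip_future_{m + 1:02d}.asc")
        write_occurrences({sp.name: sp.occurrences.records for sp in self.species},
                          out / "occurrences.csv")
        write_polygons({sp.name: sp.eoo for sp in self.species}, out / "eoo.geojson")
        manifest = {
            "seed": self.seed,
            "scenario": self.scenario,
            "design": self.design.to_dict(orient="records"),
            "niches": {sp.name: {"optima": sp.niche.optima,
                                 "tolerances": sp.niche.tolerances,
                                 "forest_dependence": sp.niche.forest_dependence}
                       for sp in self.species},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return out


def default_design() -> pd.DataFrame:
    """The packaged 18-row species/record-count design (17 unique species)."""
    with importlib.resources.files("nichecast.data").joinpath("bird_records.csv").open() as fh:
        df = pd.read_csv(fh)
    return df[["species", "records"]].copy()


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def make_terrain(seed: int, n_rows: int = DEFAULT_SHAPE[0], n_cols: int = DEFAULT_SHAPE[1],
                 cell_size: float = DEFAULT_CELL,
                 origin: tuple[float, float] = DEFAULT_ORIGIN) -> Grid:
    """Smooth seeded DEM with elevations spanning [0, 2750] m."""
    if n_rows < 10 or n_cols < 10:
        raise ValueError("terrain needs at least a 10x10 grid")
    rng = np.random.default_rng(seed)
    base = _smooth_field(rng, (n_rows, n_cols), sigma=min(n_rows, n_cols) / 8)
    ridge = _smooth_field(rng, (n_rows, n_cols), sigma=min(n_rows, n_cols) / 4)
    elev = 0.65 * base + 0.35 * ridge
    lo, hi = ELEV_RANGE
    elev = lo + (hi - lo) * (elev - elev.min()) / (elev.max() - elev.min())
    return Grid(elev, origin[0], origin[1], cell_size)


def make_climate(
    dem: Grid,
    seed: int,
    lapse_rate: float = 6.5,          # °C per km, moist-adiabatic-ish
    t_sea_level: float = 26.0,        # annual-mean coastal temperature, °C
    seasonal_amp: float = 3.0,        # half-range of the seasonal cycle, °C
    temp_noise_sd: float = 0.4,       # smooth spatial noise per month, °C
    precip_wet: float = 320.0,        # wet-season monthly rainfall scale, mm
    precip_dry: float = 25.0,         # dry-season monthly rainfall scale, mm
) -> MonthlyClimate:
    """Monthly climate driven by the DEM: lapse-cooled southern-hemisphere
    temperature cycle and a wet/dry precipitation seasonality with an
    east–west moisture gradient."""
    rng = np.random.default_rng(seed)
    shape = dem.values.shape
    elev_km = dem.values / 1000.0
    # east-west moisture gradient (east = wetter), plus patchy noise
    east = np.linspace(0.6, 1.4, shape[1])[None, :]
    wet_noise = _smooth_field(rng, shape, sigma=shape[0] / 10)
    temps: list[Grid] = []
    precips: list[Grid] = []
    for m in range(12):
        # month 0 = January: austral summer, hottest and wettest
        phase = np.cos(2 * np.pi * m / 12.0)
        t = (t_sea_level + seasonal_amp * phase - lapse_rate * elev_km)
        if temp_noise_sd > 0:
            t = t + temp_noise_sd * _smooth_field(rng, shape, sigma=shape[0] / 10)
        season_w = 0.5 * (1 + phase)  # 1 in Jan, 0 in Jul
        p = (precip_dry + (precip_wet - precip_dry) * season_w) * east
        p = p * np.exp(0.25 * wet_noise)
        p = np.maximum(p, 1.0)
        temps.append(dem.copy_with(t, dem.mask))
        precips.append(dem.copy_with(p, dem.mask))
    return MonthlyClimate(temps, precips)


def apply_scenario(mc: MonthlyClimate, delta_t: float = 2.0,
                   precip_factor: float = 1.0) -> MonthlyClimate:
    """Uniform warming scenario: +delta_t °C every month, precipitation
    scaled by ``precip_factor``."""
    if precip_factor < 0:
        raise ValueError("precip_factor must be ≥ 0")
    temps = [g.copy_with(g.values + delta_t, g.mask) for g in mc.temp]
    precips = [g.copy_with(g.values * precip_factor, g.mask) for g in mc.precip]
    return MonthlyClimate(temps, precips)


def true_suitability(stack: ClimateStack, niche: NicheParams) -> Grid:
    """Product of per-covariate Gaussian responses × forest term, scaled to
    ``max_suitability`` at a cell sitting exactly at every optimum with
    full forest cover."""
    tmpl = stack.template
    suit = np.full(tmpl.values.shape, niche.max_suitability)
    for name, opt in niche.optima.items():
        g = stack[name]
        tol = niche.tolerances[name]
        suit = suit * np.exp(-((g.values - opt) ** 2) / (2 * tol**2))
    if niche.forest_dependence > 0:
        forest = stack["forest_pct"]
        suit = suit * (np.clip(forest.values, 0, 100) / 100.0) ** niche.forest_dependence
    mask = stack.combined_mask()
    return tmpl.copy_with(np.where(mask, np.nan, suit), mask)


def sample_species(suit: Grid, n: int, seed: int, species: str = "virtual") -> OccurrenceSet:
    """Draw n distinct cells with probability proportional to suitability;
    records are placed at cell centres."""
    flat = np.where(suit.mask.ravel(), 0.0, suit.values.ravel())
    flat = np.where(np.isfinite(flat), flat, 0.0)
    positive = np.flatnonzero(flat > 0)
    if positive.size < n:
        raise ValueError(
            f"{species}: only {positive.size} cells with positive suitability, need {n}")
    rng = np.random.default_rng(seed)
    p = flat[positive] / flat[positive].sum()
    chosen = rng.choice(positive, size=n, replace=False, p=p)
    cells = [(int(i // suit.n_cols), int(i % suit.n_cols)) for i in chosen]
    coords = [suit.cell_center(r, c) for r, c in cells]
    return OccurrenceSet(species, coords, cells, cells)


def make_eoo(occ: OccurrenceSet, buffer_cells: float, cell_size: float) -> PolygonSet:
    """Extent-of-occurrence polygon: convex hull of the records buffered
    outward by ``buffer_cells`` cells (bounding box for degenerate hulls)."""
    if not occ.records:
        raise ValueError("cannot build an EOO from an empty occurrence set")
    hull = MultiPoint(occ.records).convex_hull
    if not isinstance(hull, Polygon):  # < 3 distinct non-collinear points
        hull = box(*hull.bounds).buffer(cell_size / 4)
    poly = hull.buffer(buffer_cells * cell_size)
    return PolygonSet(occ.species, [poly])


#: Covariates carrying the virtual species' climatic niche axes.
NICHE_COVARIATES = ("t_mean", "p_ann")
#: Gaussian tolerance as a fraction of each covariate's landscape sd.
#: Threatened forest-restricted endemics are habitat specialists: 0.2 puts a
#: species' high-suitability core on a few percent of the landscape.
NICHE_TOLERANCE_FRAC = 0.2
DEFAULT_FOREST_DEPENDENCE = 2.0
DEFAULT_EOO_BUFFER_CELLS = 8.0


def _draw_niche(stack: ClimateStack, rng: np.random.Generator,
                forest_dependence: float) -> NicheParams:
    """Niche centred on the covariate values of a random forested cell."""
    forest = stack["forest_pct"].values
    candidates = np.flatnonzero((~stack.combined_mask().ravel())
                                & (forest.ravel() >= 50.0))
    if candidates.size == 0:
        candidates = np.flatnonzero(~stack.combined_mask().ravel())
    home = int(rng.choice(candidates))
    optima, tolerances = {}, {}
    for name in NICHE_COVARIATES:
        vals = stack[name].values.ravel()
        optima[name] = float(vals[home])
        tolerances[name] = float(NICHE_TOLERANCE_FRAC * np.nanstd(vals))
    return NicheParams(optima, tolerances, forest_dependence)


def _make_forest_fine(dem: Grid, p_ann: Grid, seed: int, ratio: int = 3,
                      cover: float = 0.45) -> Grid:
    """Patchy binary forest at ``ratio``× finer resolution: cover tracks a
    mix of independent patchiness (70%) and annual rainfall (30%)."""
    rng = np.random.default_rng(seed)
    fine_shape = (dem.n_rows * ratio, dem.n_cols * ratio)
    patch = _smooth_field(rng, fine_shape, sigma=fine_shape[0] / 20)
    wet = np.kron(p_ann.values, np.ones((ratio, ratio)))
    wet = (wet - np.nanmean(wet)) / np.nanstd(wet)
    score = 0.7 * patch + 0.3 * wet
    thresh = np.quantile(score, 1 - cover)
    forest = (score > thresh).astype(float)
    return Grid(forest, dem.x_origin, dem.y_origin, dem.cell_size / ratio)


def make_study_fixture(
    seed: int,
    design: pd.DataFrame | None = None,
    n_rows: int = DEFAULT_SHAPE[0],
    n_cols: int = DEFAULT_SHAPE[1],
    delta_t: float = 2.0,
    precip_factor: float = 0.9,
    forest_dependence: float = DEFAULT_FOREST_DEPENDENCE,
    eoo_buffer_cells: float = DEFAULT_EOO_BUFFER_CELLS,
) -> StudyFixture:
    """Complete seeded study bundle on a fresh synthetic landscape.

    ``design`` is a DataFrame with columns ``species`` and ``records``; the
    default is the packaged 18-row table.  A species appearing in several
    rows gets one niche, with each row's records drawn separately and then
    merged into its occurrence set.
    """
    if design is None:
        design = default_design()
    design = design.reset_index(drop=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4 + 2 * len(design)) >> 1]

    dem = make_terrain(seeds[0], n_rows, n_cols)
    climate_current = make_climate(dem, seeds[1])
    climate_future = apply_scenario(climate_current, delta_t, precip_factor)
    stack_plain = derive_covariates(climate_current)
    forest_fine = _make_forest_fine(dem, stack_plain["p_ann"], seeds[2])
    forest_pct = forest_percent(forest_fine, dem)
    stack_current = derive_covariates(climate_current, forest_pct)
    stack_future = derive_covariates(climate_future, forest_pct)

    species: list[SpeciesFixture] = []
    niches: dict[str, NicheParams] = {}
    row_occ: dict[str, list[OccurrenceSet]] = {}
    rng_niche = np.random.default_rng(seeds[3])
    for i, row in design.iterrows():
        name, n_rec = str(row["species"]), int(row["records"])
        if name not in niches:
            niches[name] = _draw_niche(stack_current, rng_niche, forest_dependence)
        suit = true_suitability(stack_current, niches[name])
        occ = sample_species(suit, n_rec, seeds[4 + 2 * i], name)
        row_occ.setdefault(name, []).append(occ)
    for name in design["species"].unique():
        parts = row_occ[name]
        coords = [xy for part in parts for xy in part.records]
        occ = resolve_occurrences(name, coords, dem)
        eoo = make_eoo(occ, eoo_buffer_cells, dem.cell_size)
        rows = [len(p.records) for p in parts]
        species.append(SpeciesFixture(name, rows, niches[name], occ, eoo,
                                      true_suitability(stack_current, niches[name])))

    return StudyFixture(seed, dem, forest_fine, forest_pct, climate_current,
                        climate_future, stack_current, stack_future, species,
                        design, {"delta_t": delta_t, "precip_factor": precip_factor})
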