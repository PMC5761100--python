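"""Synthetic study-system generator with known ground truth.

Emulates everything the assignment pipeline consumes: a covariate
stack (temperature, elevation, latitude, longitude), a precipitation
δ²H isoscape that is a linear function of those covariates plus iid
noise, a set of known-origin calibration populations, a species range
mask, and migrant cohorts whose arrival phenology follows a
configurable latitude → arrival-day slope.  Every downstream stage is
therefore testable by parameter recovery: the generating coefficients
are known, and each migrant carries its true natal coordinates in a
truth table the pipeline never sees.

Default study conditions: a 25–55° N domain with an effective
latitudinal δ²H gradient near −1.5 ‰/° (latitude coefficient −1.5 ‰/°
before the small temperature-mediated contribution), ten calibration
populations totalling 186 birds, and cohorts of 25 birds per sex per
year over three years (150 birds), captured between ordinal days 237
and 305 (Aug 25 – Nov 1 in a non-leap year) with an arrival slope of
+2 days per degree of natal latitude.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .assignment import Migrant, write_migrants_csv
from .calibration import CalibrationSite, write_sites_csv
from .raster import RangeMask, RasterGrid, write_raster

__all__ = [
    "PrecipModel",
    "TissueModel",
    "PhenologyModel",
    "MorphometryModel",
    "WorldConfig",
    "World",
    "TrueMigrant",
    "make_world",
    "make_calibration_sites",
    "make_migrants",
    "write_inputs",
]

SEASON_WINDOW = (237, 305)  # ordinal days, Aug 25 – Nov 1 non-leap
COVARIATE_NAMES = ("temperature", "elevation", "latitude", "longitude")


@dataclass(frozen=True)
class PrecipModel:
    """Generating linear model for precipitation δ²H (‰)."""

    intercept: float = -14.0
    lat_slope: float = -1.5      # ‰ per degree latitude
    lon_slope: float = -0.2      # ‰ per degree longitude
    elev_slope: float = -0.015   # ‰ per metre
    temp_slope: float = 0.4      # ‰ per °C
    resid_sd: float = 3.0        # ‰


@dataclass(frozen=True)
class TissueModel:
    """True linear map from precipitation to feather δ²H."""

    intercept: float = -25.0     # ‰
    slope: float = 1.0           # dimensionless
    site_sd: float = 2.0         # ‰, bird-to-bird scatter within a site


@dataclass(frozen=True)
class PhenologyModel:
    """Arrival-day model: day = intercept + slope * natal latitude."""

    intercept: float = 192.0     # ordinal day at latitude 0
    slope: float = 2.0           # days per degree natal latitude
    resid_sd: float = 5.0        # days
    window: tuple[int, int] = SEASON_WINDOW


@dataclass(frozen=True)
class MorphometryModel:
    """Sex-specific structural size and fuel-load generators.

    Female ruby-throats are structurally larger than males, so the
    defaults give females the longer wing chords.  Fuel load is drawn
    from a gamma distribution (strictly positive, right-skewed), so
    capture mass always exceeds fat-free mass.
    """

    chord_mean: Mapping[str, float] = field(
        default_factory=lambda: {"F": 47.0, "M": 40.0})  # mm
    chord_sd: float = 1.2                                # mm
    fat_free_coeff: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"F": (0.3, 0.062), "M": (0.5, 0.055)})
    fuel_shape: float = 2.0
    fuel_scale: float = 0.35     # g; gamma mean = shape * scale = 0.7 g


@dataclass(frozen=True)
class WorldConfig:
    """Full specification of a synthetic study system."""

    lat_range: tuple[float, float] = (25.0, 55.0)
    lon_range: tuple[float, float] = (-95.0, -75.0)
    resolution: float = 0.5      # degrees per cell
    precip_model: PrecipModel = field(default_factory=PrecipModel)
    tissue_model: TissueModel = field(default_factory=TissueModel)
    phenology_model: PhenologyModel = field(default_factory=PhenologyModel)
    morphometry_model: MorphometryModel = field(default_factory=MorphometryModel)
    temp_lat_slope: float = -0.6     # °C per degree latitude
    temp_intercept: float = 38.0     # °C at latitude 0
    temp_noise_sd: float = 1.5       # °C, smoothed field
    elev_max: float = 1500.0         # m
    elev_smooth_sigma: float = 3.0   # cells
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lat_range[0] >= self.lat_range[1]:
            raise ValueError("degenerate latitude range")
        if self.lon_range[0] >= self.lon_range[1]:
            raise ValueError("degenerate longitude range")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name, sd in (("precip resid_sd", self.precip_model.resid_sd),
                         ("tissue site_sd", self.tissue_model.site_sd),
                         ("phenology resid_sd", self.phenology_model.resid_sd)):
            if sd < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class World:
    """Generated grids plus the range mask and the config that made them."""

    temperature: RasterGrid
    elevation: RasterGrid
    latitude: RasterGrid
    longitude: RasterGrid
    precip_truth: RasterGrid
    mask: RangeMask
    config: WorldConfig

    @property
    def covariates(self) -> tuple[RasterGrid, ...]:
        return (self.temperature, self.elevation, self.latitude, self.longitude)


@dataclass
class TrueMigrant(Migrant):
    """A migrant with its ground-truth natal coordinates attached.

    The truth fields are written to a separate table that the pipeline
    never reads; they exist only so tests can score recovery.
    """

    natal_lat: float = float("nan")
    natal_lon: float = float("nan")


def _rng_for(config: WorldConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.rng_seed) % (2 ** 31), stream))
    )


def make_world(config: WorldConfig) -> World:
    """Generate the covariate stack, the true isoscape and the range mask.

    The precipitation grid is exactly the stated linear combination of
    the four covariates plus iid Normal(0, resid_sd) noise.  Elevation
    is a smoothed Gaussian random field (keeps the covariate matrix
    full rank); temperature declines smoothly with latitude plus a
    small smoothed field.
    """
    rng = _rng_for(config, 0)
    lat0, lat1 = config.lat_range
    lon0, lon1 = config.lon_range
    res = config.resolution
    n_rows = int(round((lat1 - lat0) / res))
    n_cols = int(round((lon1 - lon0) / res))
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2; shrink the resolution")

    def blank() -> RasterGrid:
        return RasterGrid(
            values=np.zeros((n_rows, n_cols)),
            origin_lon=lon0, origin_lat=lat1,
            cell_size_lon=res, cell_size_lat=-res,
        )

    ref = blank()
    lon_grid, lat_grid = ref.cell_centers()

    def smooth_field(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros((n_rows, n_cols))
        raw = rng.standard_normal((n_rows, n_cols))
        sm = ndimage.gaussian_filter(raw, sigma=config.elev_smooth_sigma,
                                     mode="reflect")
        std = sm.std()
        return sm / std * sd if std > 0 else sm

    elev_field = smooth_field(1.0)
    elevation = (elev_field - elev_field.min())
    span = elevation.max()
    elevation = elevation / span * config.elev_max if span > 0 else elevation

    temperature = (config.temp_intercept
                   + config.temp_lat_slope * lat_grid
                   + smooth_field(config.temp_noise_sd))

    pm = config.precip_model
    precip = (pm.intercept
              + pm.temp_slope * temperature
              + pm.elev_slope * elevation
              + pm.lat_slope * lat_grid
              + pm.lon_slope * lon_grid
              + pm.resid_sd * rng.standard_normal((n_rows, n_cols)))

    mask = RangeMask(ref.with_values(np.ones((n_rows, n_cols))),
                     description="synthetic breeding range (full domain)")
    return World(
        temperature=ref.with_values(temperature),
        elevation=ref.with_values(elevation),
        latitude=ref.with_values(lat_grid),
        longitude=ref.with_values(lon_grid),
        precip_truth=ref.with_values(precip),
        mask=mask,
        config=config,
    )


def _allocate_evenly(total: int, bins: int) -> list[int]:
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def make_calibration_sites(
    world: World,
    n_sites: int = 10,
    birds_per_site: int | Sequence[int] | None = None,
    total_birds: int = 186,
) -> list[CalibrationSite]:
    """Simulate known-origin breeding populations inside the range.

    Sites are stratified across the latitudinal span of the range mask
    so the calibration regression always sees a spread of environmental
    values.  Per-bird feather values apply the tissue model to the
    site's true precipitation value plus Normal(0, site_sd) noise; the
    reported feather mean/SD/n are computed from those draws.  By
    default 186 birds are split as evenly as possible across 10 sites.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites for the calibration regression")
    rng = _rng_for(world.config, 1)
    inside_rows, inside_cols = np.nonzero(world.mask.inside())
    if n_sites > inside_rows.size:
        raise ValueError(
            f"n_sites={n_sites} exceeds {inside_rows.size} valid range cells"
        )
    if birds_per_site is None:
        counts = _allocate_evenly(total_birds, n_sites)
    elif isinstance(birds_per_site, int):
        counts = [birds_per_site] * n_sites
    else:
        counts = list(birds_per_site)
        if len(counts) != n_sites:
            raise ValueError("birds_per_site list must have n_sites entries")

    # stratify by latitude: order range cells north to south, take one
    # cell per quantile band (jittered within the band)
    lats = world.latitude.values[inside_rows, inside_cols]
    order = np.argsort(lats)
    bands = np.array_split(order, n_sites)
    tm = world.config.tissue_model
    sites: list[CalibrationSite] = []
    for i, band in enumerate(bands):
        pick = band[rng.integers(band.size)]
        row, col = inside_rows[pick], inside_cols[pick]
        lon, lat = world.precip_truth.cell_center(row, col)
        precip = world.precip_truth.values[row, col]
        n = counts[i]
        feathers = (tm.intercept + tm.slope * precip
                    + tm.site_sd * rng.standard_normal(n))
        sd = float(feathers.std(ddof=1)) if n > 1 else 0.0
        sites.append(CalibrationSite(
            site_id=f"site_{i + 1:02d}",
            lon=lon, lat=lat,
            feather_mean=float(feathers.mean()),
            feather_sd=sd,
            n_birds=int(n),
            env_d2h=float(precip),
        ))
    return sites


def make_migrants(
    world: World,
    per_year: Mapping[int, int] | None = None,
    per_sex_split: bool = True,
) -> list[TrueMigrant]:
    """Simulate a migrant cohort with known natal origins.

    Natal cells are drawn uniformly from range-mask cells.  The feather
    value applies the tissue model to the true precipitation value at
    the natal cell plus site-level noise.  Arrival day is phenology
    intercept + slope × natal latitude + noise, redrawn (up to 100
    attempts, then clamped) until it falls inside the season window so
    the window edges show no pile-up.  Capture mass is sex-specific
    fat-free mass (from the wing-chord regression) plus a strictly
    positive gamma fuel load.
    """
    if per_year is None:
        per_year = {2010: 50, 2011: 50, 2014: 50}
    if any(n <= 0 for n in per_year.values()):
        raise ValueError("per-year counts must be positive")
    rng = _rng_for(world.config, 2)
    inside_rows, inside_cols = np.nonzero(world.mask.inside())
    tm = world.config.tissue_model
    ph = world.config.phenology_model
    mm = world.config.morphometry_model
    lo, hi = ph.window

    migrants: list[TrueMigrant] = []
    for year in sorted(per_year):
        n_year = per_year[year]
        if per_sex_split:
            sexes = ["F"] * (n_year // 2) + ["M"] * (n_year - n_year // 2)
        else:
            sexes = list(rng.choice(["F", "M"], size=n_year))
        for k, sex in enumerate(sexes):
            pick = rng.integers(inside_rows.size)
            row, col = inside_rows[pick], inside_cols[pick]
            natal_lon, natal_lat = world.precip_truth.cell_center(row, col)
            precip = world.precip_truth.values[row, col]
            feather = (tm.intercept + tm.slope * precip
                       + tm.site_sd * rng.standard_normal())

            base_day = ph.intercept + ph.slope * natal_lat
            day = base_day + ph.resid_sd * rng.standard_normal()
            for _ in range(100):
                if lo <= day <= hi:
                    break
                day = base_day + ph.resid_sd * rng.standard_normal()
            day = int(round(min(max(day, lo), hi)))

            chord = mm.chord_mean[sex] + mm.chord_sd * rng.standard_normal()
            a, b = mm.fat_free_coeff[sex]
            ffm = a + b * chord
            fuel = rng.gamma(mm.fuel_shape, mm.fuel_scale)
            capture = _dt.date(year, 1, 1) + _dt.timedelta(days=day - 1)

            migrants.append(TrueMigrant(
                bird_id=f"Y{year}_{sex}{k + 1:03d}",
                sex=sex,
                year=year,
                capture_date=capture,
                ordinal_day=capture.timetuple().tm_yday,
                mass_g=float(ffm + fuel),
                wing_chord_mm=float(chord),
                feather_d2h=float(feather),
                natal_lat=float(natal_lat),
                natal_lon=float(natal_lon),
            ))
    return migrants


def write_inputs(
    world: World,
    sites: Sequence[CalibrationSite],
    migrants: Sequence[TrueMigrant],
    outdir: str | Path,
    raster_format: str = "ascii_grid",
) -> dict[str, Path]:
    """Write the standard pipeline inputs plus a separate truth table.

    The truth table (natal coordinates) is never read by the pipeline;
    it exists so an analyst can score recovery afterwards.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if raster_format == "ascii_grid" else ".tif"
    paths: dict[str, Path] = {}
    for name, grid in zip(COVARIATE_NAMES, world.covariates):
        paths[name] = outdir / f"{name}{ext}"
        write_raster(grid, paths[name], raster_format)
    paths["precip_d2h"] = outdir / f"precip_d2h{ext}"
    write_raster(world.precip_truth, paths["precip_d2h"], raster_format)
    paths["range_mask"] = outdir / f"range_mask{ext}"
    write_raster(world.mask.grid, paths["range_mask"], raster_format)

    paths["sites"] = outdir / "calibration_sites.csv"
    write_sites_csv(sites, paths["sites"])
    paths["migrants"] = outdir / "migrants.csv"
    write_migrants_csv(migrants, paths["migrants"])
    paths["truth"] = outdir / "migrants_truth.csv"
    pd.DataFrame([
        {"bird_id": m.bird_id, "natal_lat": m.natal_lat,
         "natal_lon": m.natal_lon}
        for m in migrants
    ]).to_csv(paths["truth"], index=False)
    return paths
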