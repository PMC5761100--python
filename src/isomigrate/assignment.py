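"""Likelihood-based natal-origin assignment and spatial centroids.

For each migrant, the probability that a grid cell is its natal origin
is the normal likelihood of the observed feather δ²H given the
cellwise feather-isoscape mean and combined SD, constrained to the
species breeding range and normalized to unit mass.  A point estimate
of natal location is the probability-weighted spatial centroid of the
top fraction of cells, after random resampling of the retained cells.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import RangeMask, RasterGrid, apply_mask

__all__ = [
    "Migrant",
    "AssignmentSurface",
    "Centroid",
    "likelihood_surface",
    "centroid_top_fraction",
    "assign_cohort",
    "read_migrants_csv",
    "write_migrants_csv",
]

logger = logging.getLogger(__name__)

NORMALIZATION_TOL = 1e-9
DEFAULT_TOP_FRACTION = 0.10
DEFAULT_N_RESAMPLE = 100


@dataclass
class Migrant:
    """One sampled bird with raw and derived measurements."""

    bird_id: str
    sex: str
    year: int
    capture_date: _dt.date | None
    ordinal_day: int
    mass_g: float
    wing_chord_mm: float
    feather_d2h: float
    fat_free_mass_g: float | None = None
    fuel_load_g: float | None = None
    centroid_lat: float | None = None
    centroid_lon: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in {"F", "M"}:
            raise ValueError(f"bird {self.bird_id}: sex must be F or M")
        if self.capture_date is not None:
            doy = self.capture_date.timetuple().tm_yday
            if doy != self.ordinal_day:
                raise ValueError(
                    f"bird {self.bird_id}: ordinal_day {self.ordinal_day} "
                    f"inconsistent with capture date {self.capture_date}"
                )


@dataclass
class AssignmentSurface:
    """Normalized, range-constrained natal-origin probability raster."""

    bird_id: str
    probs: RasterGrid
    normalization: bool = True

    def __post_init__(self) -> None:
        vals = self.probs.valid_values()
        if vals.size == 0:
            raise ValueError(f"bird {self.bird_id}: empty probability support")
        if np.any(vals < 0):
            raise ValueError(f"bird {self.bird_id}: negative probabilities")
        if abs(vals.sum() - 1.0) > NORMALIZATION_TOL:
            raise ValueError(
                f"bird {self.bird_id}: probabilities sum to {vals.sum()!r}, "
                "expected 1"
            )


@dataclass
class Centroid:
    """Probability-weighted geographic mean of the top-probability cells."""

    bird_id: str
    lat: float
    lon: float
    mean_top_prob: float
    n_cells_top: int
    n_resampled: int
    seed: int


def likelihood_surface(
    feather_d2h: float,
    feather_surface: RasterGrid,
    feather_sd_surface: RasterGrid,
    mask: RangeMask,
    bird_id: str = "",
) -> AssignmentSurface:
    """Normal-likelihood assignment surface for one feather value.

    Log-likelihoods are accumulated with max-subtraction before
    exponentiation so large grids cannot underflow.  Any masked-in cell
    with zero SD is rejected outright.
    """
    feather_surface.require_aligned(feather_sd_surface, "SD surface")
    feather_surface.require_aligned(mask.grid, "range mask")
    inside = mask.inside() & feather_surface.valid_mask() \
        & feather_sd_surface.valid_mask()
    if not np.any(inside):
        raise ValueError("empty support: no valid cells inside the range mask")
    mu = feather_surface.values[inside]
    sigma = feather_sd_surface.values[inside]
    if np.any(sigma <= 0):
        raise ValueError(
            "zero or negative SD at masked-in cells; the combined SD surface "
            "must be strictly positive inside the range"
        )
    loglik = -0.5 * ((feather_d2h - mu) / sigma) ** 2 - np.log(sigma)
    lik = np.exp(loglik - loglik.max())
    probs = lik / lik.sum()
    out = np.full(feather_surface.shape, feather_surface.nodata_value)
    out[inside] = probs
    grid = feather_surface.with_values(out)
    return AssignmentSurface(bird_id=bird_id, probs=grid)


def centroid_top_fraction(
    surface: AssignmentSurface,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int = 0,
    weighted_draw: bool = False,
) -> Centroid:
    """Spatial centroid of the resampled top-probability cells.

    Cells are ranked by probability and the top ``ceil(top_fraction *
    n_valid)`` retained; ``n_resample`` cells are then drawn from the
    retained set (uniformly by default, probability-weighted when
    ``weighted_draw``; without replacement when the retained set is at
    least ``n_resample`` strong, with replacement otherwise).  The
    centroid is the probability-weighted mean of the resampled cells'
    center coordinates.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    if n_resample < 1:
        raise ValueError("n_resample must be positive")
    grid = surface.probs
    valid = grid.valid_mask()
    rows, cols = np.nonzero(valid)
    probs = grid.values[valid]
    n_keep = int(np.ceil(top_fraction * probs.size))
    order = np.argsort(probs)[::-1][:n_keep]
    keep_rows, keep_cols, keep_probs = rows[order], cols[order], probs[order]

    rng = np.random.default_rng(seed)
    replace = n_keep < n_resample
    p = keep_probs / keep_probs.sum() if weighted_draw else None
    idx = rng.choice(n_keep, size=n_resample, replace=replace, p=p)

    lon_grid, lat_grid = grid.cell_centers()
    lons = lon_grid[keep_rows[idx], keep_cols[idx]]
    lats = lat_grid[keep_rows[idx], keep_cols[idx]]
    w = keep_probs[idx]
    wsum = w.sum()
    return Centroid(
        bird_id=surface.bird_id,
        lat=float((w * lats).sum() / wsum),
        lon=float((w * lons).sum() / wsum),
        mean_top_prob=float(keep_probs[idx].mean()),
        n_cells_top=int(n_keep),
        n_resampled=int(n_resample),
        seed=int(seed),
    )


def bird_seed(master_seed: int, bird_id: str) -> int:
    """Deterministic per-bird seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(bird_id.encode())) % (2 ** 31)


def assign_cohort(
    migrants: Sequence[Migrant],
    feather_surface: RasterGrid,
    feather_sd_surface: RasterGrid,
    mask: RangeMask,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int = 0,
    weighted_draw: bool = False,
) -> tuple[list[AssignmentSurface], list[Centroid], dict[str, str]]:
    """Per-bird assignment surfaces and centroids for a whole cohort.

    Per-bird randomness derives deterministically from the master seed
    and the bird id.  Per-bird failures are collected (id → message)
    and returned without aborting the cohort; the migrants' centroid
    fields are filled in place.
    """
    if not migrants:
        raise ValueError("empty cohort")
    surfaces: list[AssignmentSurface] = []
    centroids: list[Centroid] = []
    failures: dict[str, str] = {}
    for bird in migrants:
        try:
            surf = likelihood_surface(
                bird.feather_d2h, feather_surface, feather_sd_surface,
                mask, bird_id=bird.bird_id,
            )
            cen = centroid_top_fraction(
                surf, top_fraction=top_fraction, n_resample=n_resample,
                seed=bird_seed(seed, bird.bird_id),
                weighted_draw=weighted_draw,
            )
        except (ValueError, ArithmeticError) as exc:
            failures[bird.bird_id] = str(exc)
            continue
        bird.centroid_lat, bird.centroid_lon = cen.lat, cen.lon
        surfaces.append(surf)
        centroids.append(cen)
    if failures:
        logger.warning("assignment failed for %d bird(s): %s",
                       len(failures), sorted(failures))
    return surfaces, centroids, failures


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_MIGRANT_COLUMNS = [
    "bird_id", "sex", "year", "capture_date", "ordinal_day", "mass_g",
    "wing_chord_mm", "feather_d2h", "fat_free_mass_g", "fuel_load_g",
    "centroid_lat", "centroid_lon",
]


def write_migrants_csv(migrants: Sequence[Migrant], path) -> None:
    rows = []
    for m in migrants:
        rec = {c: getattr(m, c) for c in _MIGRANT_COLUMNS}
        rec["capture_date"] = (
            m.capture_date.isoformat() if m.capture_date else ""
        )
        rows.append(rec)
    pd.DataFrame(rows, columns=_MIGRANT_COLUMNS).to_csv(path, index=False)


def read_migrants_csv(path) -> list[Migrant]:
    df = pd.read_csv(path)
    required = {"bird_id", "sex", "year", "ordinal_day", "mass_g",
                "wing_chord_mm", "feather_d2h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"migrants CSV missing columns {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        date_str = rec.get("capture_date")
        date = (_dt.date.fromisoformat(str(date_str))
                if isinstance(date_str, str) and date_str else None)

        def _opt(key):
            v = rec.get(key)
            return None if v is None or pd.isna(v) else float(v)

        out.append(Migrant(
            bird_id=str(rec["bird_id"]),
            sex=str(rec["sex"]),
            year=int(rec["year"]),
            capture_date=date,
            ordinal_day=int(rec["ordinal_day"]),
            mass_g=float(rec["mass_g"]),
            wing_chord_mm=float(rec["wing_chord_mm"]),
            feather_d2h=float(rec["feather_d2h"]),
            fat_free_mass_g=_opt("fat_free_mass_g"),
            fuel_load_g=_opt("fuel_load_g"),
            centroid_lat=_opt("centroid_lat"),
            centroid_lon=_opt("centroid_lon"),
        ))
    return out
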