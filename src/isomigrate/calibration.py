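"""Isoscape-to-feather rescaling via a site-resampling bootstrap.

Known-origin breeding populations provide feather δ²H summary
statistics (mean, SD, n) that are paired with the environmental
(precipitation) δ²H at each site.  Each bootstrap replicate draws one
feather value per site from Normal(mean, SD) — and one environmental
value from Normal(env, env_sd) when a precipitation-side SD is
available — then fits a simple linear regression of feather on
environmental δ²H.  The empirical mean and SD of the replicate
intercepts, slopes and residual SDs summarize the rescaling transfer
function and its uncertainty, which are then pushed through the
precipitation isoscape cellwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "CalibrationSite",
    "RescaleModel",
    "bootstrap_rescale",
    "convert_isoscape",
    "read_sites_csv",
    "write_sites_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000


@dataclass
class CalibrationSite:
    """One known-origin breeding population used for calibration."""

    site_id: str
    lon: float
    lat: float
    feather_mean: float
    feather_sd: float
    n_birds: int
    env_d2h: float = np.nan
    env_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.feather_sd < 0:
            raise ValueError(f"site {self.site_id}: feather_sd must be >= 0")
        if self.n_birds < 1:
            raise ValueError(f"site {self.site_id}: n_birds must be >= 1")


@dataclass
class RescaleModel:
    """Bootstrap summary of the feather ~ precipitation regression."""

    intercept_mean: float
    slope_mean: float
    intercept_sd: float
    slope_sd: float
    resid_sd_mean: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        for name in ("intercept_sd", "slope_sd", "resid_sd_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in ("intercept_mean", "slope_mean", "intercept_sd",
                         "slope_sd", "resid_sd_mean", "n_boot", "seed"):
                fh.write(f"{name} {getattr(self, name)!r}\n")
            fh.write("# cell SD combines rescaling uncertainty and the "
                     "slope-scaled isoscape prediction SE in quadrature\n")

    @classmethod
    def load(cls, path: str | Path) -> "RescaleModel":
        fields: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                key, _, rest = line.partition(" ")
                fields[key] = rest.strip()
        return cls(
            intercept_mean=float(fields["intercept_mean"]),
            slope_mean=float(fields["slope_mean"]),
            intercept_sd=float(fields["intercept_sd"]),
            slope_sd=float(fields["slope_sd"]),
            resid_sd_mean=float(fields["resid_sd_mean"]),
            n_boot=int(fields["n_boot"]),
            seed=int(fields["seed"]),
        )


def bootstrap_rescale(
    sites: Sequence[CalibrationSite],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    weighted: bool = False,
) -> RescaleModel:
    """Bootstrap the feather ~ environmental δ²H rescaling regression.

    One value per site is drawn per replicate (within-site resampling;
    sites themselves are not resampled).  Sites reporting a single bird
    contribute their mean without feather-side noise.  ``weighted``
    switches on per-site ``n_birds`` weights in each replicate fit
    (default off: unweighted OLS).
    """
    if len(sites) < 3:
        raise ValueError("at least 3 calibration sites required")
    env = np.array([s.env_d2h for s in sites])
    if not np.all(np.isfinite(env)):
        bad = [s.site_id for s in sites if not np.isfinite(s.env_d2h)]
        raise ValueError(f"sites without environmental δ²H: {bad}")
    if np.unique(env).size < 2:
        raise ValueError("degenerate design: all sites share one "
                         "environmental δ²H value")
    singletons = [s.site_id for s in sites if s.n_birds == 1 or s.feather_sd == 0]
    if singletons:
        logger.warning(
            "sites %s contribute their mean with no feather-side noise",
            singletons,
        )

    rng = np.random.default_rng(seed)
    feather_mean = np.array([s.feather_mean for s in sites])
    feather_sd = np.array([s.feather_sd for s in sites])
    env_sd = np.array([s.env_sd for s in sites])
    n_sites = len(sites)

    # (n_boot, n_sites) draws; vectorized per-replicate simple regression
    f = feather_mean + feather_sd * rng.standard_normal((n_boot, n_sites))
    e = env + env_sd * rng.standard_normal((n_boot, n_sites))
    if weighted:
        w = np.array([s.n_birds for s in sites], dtype=float)
        w = np.broadcast_to(w / w.sum(), e.shape)
    else:
        w = np.full_like(e, 1.0 / n_sites)
    e_bar = (w * e).sum(axis=1, keepdims=True)
    f_bar = (w * f).sum(axis=1, keepdims=True)
    sxx = (w * (e - e_bar) ** 2).sum(axis=1)
    sxy = (w * (e - e_bar) * (f - f_bar)).sum(axis=1)
    slope = sxy / sxx
    intercept = f_bar[:, 0] - slope * e_bar[:, 0]
    resid = f - (intercept[:, None] + slope[:, None] * e)
    dof = max(n_sites - 2, 1)
    resid_sd = np.sqrt((resid ** 2).sum(axis=1) / dof)

    return RescaleModel(
        intercept_mean=float(intercept.mean()),
        slope_mean=float(slope.mean()),
        intercept_sd=float(intercept.std(ddof=0)),
        slope_sd=float(slope.std(ddof=0)),
        resid_sd_mean=float(resid_sd.mean()),
        n_boot=int(n_boot),
        seed=int(seed),
    )


def convert_isoscape(
    precip_surface: RasterGrid,
    precip_se_surface: RasterGrid | None,
    model: RescaleModel,
) -> tuple[RasterGrid, RasterGrid]:
    """Rescale the precipitation isoscape to feather δ²H cellwise.

    The feather surface is ``intercept_mean + slope_mean * precip``.
    The SD surface combines, in quadrature (independence assumed), the
    rescaling uncertainty — intercept SD, slope SD scaled by |precip|,
    mean residual SD — and the isoscape prediction SE scaled by
    |slope_mean|.
    """
    if precip_se_surface is not None:
        precip_surface.require_aligned(precip_se_surface, "isoscape SE surface")
    valid = precip_surface.valid_mask()
    if precip_se_surface is not None:
        valid = valid & precip_se_surface.valid_mask()
        se_vals = precip_se_surface.values
    else:
        se_vals = np.zeros(precip_surface.shape)
    p = precip_surface.values
    nodata = precip_surface.nodata_value

    feather = np.full(precip_surface.shape, nodata)
    sd = np.full(precip_surface.shape, nodata)
    feather[valid] = model.intercept_mean + model.slope_mean * p[valid]
    sd[valid] = np.sqrt(
        model.intercept_sd ** 2
        + (model.slope_sd * np.abs(p[valid])) ** 2
        + model.resid_sd_mean ** 2
        + (model.slope_mean * se_vals[valid]) ** 2
    )
    return precip_surface.with_values(feather), precip_surface.with_values(sd)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["site_id", "lon", "lat", "feather_mean", "feather_sd",
                 "n_birds", "env_d2h", "env_sd"]


def write_sites_csv(sites: Sequence[CalibrationSite], path: str | Path) -> None:
    pd.DataFrame([
        {c: getattr(s, c) for c in _SITE_COLUMNS} for s in sites
    ]).to_csv(path, index=False)


def read_sites_csv(path: str | Path) -> list[CalibrationSite]:
    df = pd.read_csv(path)
    required = {"site_id", "lon", "lat", "feather_mean", "feather_sd", "n_birds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites CSV missing columns {sorted(missing)}")
    out = []
    for rec in df.to_dict("records"):
        out.append(CalibrationSite(
            site_id=str(rec["site_id"]),
            lon=float(rec["lon"]),
            lat=float(rec["lat"]),
            feather_mean=float(rec["feather_mean"]),
            feather_sd=float(rec["feather_sd"]),
            n_birds=int(rec["n_birds"]),
            env_d2h=float(rec.get("env_d2h", np.nan)),
            env_sd=float(rec.get("env_sd", 0.0) or 0.0),
        ))
    return out
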