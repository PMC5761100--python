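"""End-to-end orchestration: simulate → isoscape → calibrate → assign →
morphometrics → temporal fit.

One :class:`RunConfig` drives the whole chain with reproducible
seeding; every intermediate artifact is written to the output
directory and a JSON manifest records input checksums, derived seeds,
parameter values, stage timings and output paths so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import assignment as asg
from . import calibration as cal
from . import isoscape as iso
from . import morphometrics as morph
from . import synthetic as syn
from . import temporal as temp
from .raster import RangeMask, read_raster, write_raster

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "isoscape", "calibrate", "assign", "temporal")


@dataclass
class RunConfig:
    """Parameters for one pipeline run.

    The stage defaults mirror the procedure constants of the assignment
    protocol: 1000 bootstrap draws for the rescaling regression, the
    top 10% of cells retained per bird, 100 resampled values per
    centroid, and a default simulated cohort of 25 birds per sex per
    year over three years.
    """

    outdir: str = "isomigrate_run"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is False
    precip_path: str | None = None
    covariate_paths: tuple[str, ...] = ()
    covariate_names: tuple[str, ...] = syn.COVARIATE_NAMES
    mask_path: str | None = None
    sites_path: str | None = None
    migrants_path: str | None = None
    # synthetic world overrides (field name → value, nested models as dicts)
    world: dict[str, Any] = field(default_factory=dict)
    per_year: dict[int, int] = field(
        default_factory=lambda: {2010: 50, 2011: 50, 2014: 50})
    n_sites: int = 10
    calibration_birds: int = 186
    # stage parameters (procedure constants)
    n_boot: int = 1000
    top_fraction: float = 0.10
    n_resample: int = 100
    alpha: float = 0.05
    basis_df: int = 5
    # fat-free mass regression; None → synthetic generator truth
    fat_free_coeff: dict[str, tuple[float, float]] | None = None
    raster_format: str = "ascii_grid"
    write_surfaces: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "per_year" in raw:
            raw["per_year"] = {int(k): int(v) for k, v in raw["per_year"].items()}
        if "fat_free_coeff" in raw:
            raw["fat_free_coeff"] = {
                k: tuple(v) for k, v in raw["fat_free_coeff"].items()}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: SeedSequence((master, index))."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence((int(self.seed) % (2 ** 31), idx))
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def build_world_config(self) -> syn.WorldConfig:
        overrides = dict(self.world)
        for name, klass in (("precip_model", syn.PrecipModel),
                            ("tissue_model", syn.TissueModel),
                            ("phenology_model", syn.PhenologyModel),
                            ("morphometry_model", syn.MorphometryModel)):
            if name in overrides and isinstance(overrides[name], dict):
                overrides[name] = klass(**overrides[name])
        for name in ("lat_range", "lon_range"):
            if name in overrides:
                overrides[name] = tuple(overrides[name])
        overrides.setdefault("rng_seed", self.stage_seed("simulate"))
        return syn.WorldConfig(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    A stage failure aborts the run with the stage name attached; the
    partial output directory is kept with a ``.partial`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".partial"
    marker.touch()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    manifest: dict[str, Any] = {
        "parameters": {
            "seed": config.seed,
            "n_boot": config.n_boot,
            "top_fraction": config.top_fraction,
            "n_resample": config.n_resample,
            "alpha": config.alpha,
            "basis_df": config.basis_df,
            "per_year": {str(k): v for k, v in config.per_year.items()},
            "n_sites": config.n_sites,
            "calibration_birds": config.calibration_birds,
        },
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "inputs": {},
        "outputs": {},
        "timings_s": {},
    }
    ext = ".asc" if config.raster_format == "ascii_grid" else ".tif"

    def _record_outputs(**paths: Path) -> None:
        for key, p in paths.items():
            manifest["outputs"][key] = str(p)

    stage = "setup"
    try:
        # ---- inputs: simulate or load ---------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        truth_coeff = None
        if config.simulate:
            wc = config.build_world_config()
            world = syn.make_world(wc)
            sites = syn.make_calibration_sites(
                world, n_sites=config.n_sites,
                total_birds=config.calibration_birds)
            migrants = syn.make_migrants(world, per_year=config.per_year)
            input_paths = syn.write_inputs(
                world, sites, migrants, outdir / "inputs",
                raster_format=config.raster_format)
            truth_coeff = dict(wc.morphometry_model.fat_free_coeff)
            precip = world.precip_truth
            covariates = list(world.covariates)
            covariate_names = syn.COVARIATE_NAMES
            mask = world.mask
            birds = [asg.Migrant(**{
                f.name: getattr(m, f.name)
                for f in dataclasses.fields(asg.Migrant)
            }) for m in migrants]
            manifest["inputs"] = {k: str(v) for k, v in input_paths.items()}
        else:
            required = {"precip_path": config.precip_path,
                        "mask_path": config.mask_path,
                        "sites_path": config.sites_path,
                        "migrants_path": config.migrants_path}
            missing = [k for k, v in required.items() if not v]
            if missing or not config.covariate_paths:
                missing += [] if config.covariate_paths else ["covariate_paths"]
                raise ValueError(f"missing input config fields: {missing}")
            precip = read_raster(config.precip_path)
            covariates = [read_raster(p) for p in config.covariate_paths]
            covariate_names = tuple(config.covariate_names)
            mask = RangeMask(read_raster(config.mask_path))
            sites = cal.read_sites_csv(config.sites_path)
            birds = asg.read_migrants_csv(config.migrants_path)
            manifest["inputs"] = {
                "precip": config.precip_path,
                "mask": config.mask_path,
                "sites": config.sites_path,
                "migrants": config.migrants_path,
                **{n: p for n, p in zip(covariate_names,
                                        config.covariate_paths)},
            }
        manifest["input_checksums"] = {
            k: _sha256(Path(v)) for k, v in manifest["inputs"].items()
        }
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        # ---- isoscape regression --------------------------------------
        stage = "isoscape"
        t0 = time.perf_counter()
        model = iso.fit_isoscape(precip, covariates,
                                 covariate_names=covariate_names)
        mean_surface, se_surface = iso.predict_isoscape(model, covariates)
        model_path = outdir / "isoscape_model.txt"
        model.save(model_path)
        mean_path = outdir / f"precip_isoscape{ext}"
        se_path = outdir / f"precip_isoscape_se{ext}"
        write_raster(mean_surface, mean_path, config.raster_format)
        write_raster(se_surface, se_path, config.raster_format)
        _record_outputs(isoscape_model=model_path,
                        precip_isoscape=mean_path, precip_isoscape_se=se_path)
        manifest["isoscape"] = {
            "r_squared": model.r_squared,
            "residual_sd": model.residual_sd,
            "n_cells_fit": model.n_cells_fit,
            "coefficients": dict(zip(("intercept", *covariate_names),
                                     model.coefficients.tolist())),
        }
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        # ---- calibration ----------------------------------------------
        stage = "calibrate"
        t0 = time.perf_counter()
        coords = [(s.lon, s.lat) for s in sites]
        env = iso.extract_at_sites(mean_surface, coords)
        env_sd = iso.extract_at_sites(se_surface, coords)
        for s, e, esd in zip(sites, env, env_sd):
            s.env_d2h, s.env_sd = e, esd
        rescale = cal.bootstrap_rescale(
            sites, n_boot=config.n_boot, seed=config.stage_seed("calibrate"))
        feather_surface, feather_sd_surface = cal.convert_isoscape(
            mean_surface, se_surface, rescale)
        rescale_path = outdir / "rescale_model.txt"
        rescale.save(rescale_path)
        feather_path = outdir / f"feather_isoscape{ext}"
        feather_sd_path = outdir / f"feather_isoscape_sd{ext}"
        write_raster(feather_surface, feather_path, config.raster_format)
        write_raster(feather_sd_surface, feather_sd_path, config.raster_format)
        sites_out = outdir / "calibration_sites_env.csv"
        cal.write_sites_csv(sites, sites_out)
        _record_outputs(rescale_model=rescale_path,
                        feather_isoscape=feather_path,
                        feather_isoscape_sd=feather_sd_path,
                        calibration_sites=sites_out)
        manifest["calibration"] = {
            "slope_mean": rescale.slope_mean,
            "intercept_mean": rescale.intercept_mean,
            "slope_sd": rescale.slope_sd,
            "intercept_sd": rescale.intercept_sd,
        }
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        # ---- morphometrics --------------------------------------------
        stage = "morphometrics"
        t0 = time.perf_counter()
        coeff = config.fat_free_coeff or truth_coeff
        if coeff is None:
            raise ValueError("fat_free_coeff is required when the cohort "
                             "is not simulated")
        ff_model = morph.FatFreeModel(
            coefficients={k: tuple(v) for k, v in coeff.items()},
            provenance="run config" if config.fat_free_coeff
            else "synthetic generator truth")
        for b in birds:
            b.fat_free_mass_g = morph.fat_free_mass(
                b.wing_chord_mm, b.sex, ff_model)
            b.fuel_load_g = morph.fuel_load(b.mass_g, b.fat_free_mass_g)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        # ---- assignment ------------------------------------------------
        stage = "assign"
        t0 = time.perf_counter()
        surfaces, centroids, failures = asg.assign_cohort(
            birds, feather_surface, feather_sd_surface, mask,
            top_fraction=config.top_fraction,
            n_resample=config.n_resample,
            seed=config.stage_seed("assign"))
        if config.write_surfaces:
            surf_dir = outdir / "surfaces"
            surf_dir.mkdir(exist_ok=True)
            for s in surfaces:
                write_raster(s.probs, surf_dir / f"{s.bird_id}_assign{ext}",
                             config.raster_format)
            manifest["outputs"]["surfaces_dir"] = str(surf_dir)
        centroid_path = outdir / "centroids.csv"
        pd.DataFrame([
            {"bird_id": c.bird_id, "lat": c.lat, "lon": c.lon,
             "n_cells_top": c.n_cells_top, "mean_top_prob": c.mean_top_prob}
            for c in centroids
        ]).to_csv(centroid_path, index=False)
        augmented_path = outdir / "migrants_augmented.csv"
        asg.write_migrants_csv(birds, augmented_path)
        _record_outputs(centroids=centroid_path, migrants=augmented_path)
        manifest["assignment"] = {
            "n_assigned": len(centroids),
            "failed_ids": sorted(failures),
        }
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        # ---- temporal model --------------------------------------------
        stage = "temporal"
        t0 = time.perf_counter()
        table = pd.DataFrame([
            {"bird_id": b.bird_id, "year": b.year,
             "ordinal_day": b.ordinal_day,
             "fat_free_mass_g": b.fat_free_mass_g,
             "fuel_load_g": b.fuel_load_g,
             "centroid_lat": b.centroid_lat}
            for b in birds
        ])
        screen = temp.screen_predictors(table)
        fit = temp.fit_latitude_model(table, basis_df=config.basis_df,
                                      alpha=config.alpha)
        pattern = temp.classify_pattern(fit)
        report = {
            "classification": pattern,
            "fit": fit.to_dict(),
            "spearman_screen": screen.round(6).to_dict(),
        }
        report_path = outdir / "temporal_fit.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        _record_outputs(temporal_fit=report_path)
        manifest["temporal"] = {
            "classification": pattern,
            "arrival_p_value": fit.arrival.p_value,
            "arrival_direction": fit.arrival.direction,
        }
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest["outputs"]["manifest"] = str(manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    marker.unlink(missing_ok=True)
    return manifest
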