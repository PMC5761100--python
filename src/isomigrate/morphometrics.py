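"""Body-condition derivations for captured migrants.

Fat-free body mass is predicted from structural size (natural wing
chord) with a sex-specific linear regression supplied by the user or
the synthetic generator; fuel load is the difference between capture
mass and fat-free mass and serves as a proxy for energetic stores.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

__all__ = ["FatFreeModel", "fat_free_mass", "fuel_load", "ordinal_day"]

logger = logging.getLogger(__name__)

#: plausible natural wing-chord window (mm) for a small hummingbird
DEFAULT_CHORD_WINDOW = (30.0, 60.0)


@dataclass(frozen=True)
class FatFreeModel:
    """Sex-specific linear map from wing chord (mm) to fat-free mass (g).

    ``coefficients`` maps sex code ("F" or "M") to ``(intercept_g,
    slope_g_per_mm)``.  The coefficients are a required input — they
    come from a banding-data regression on zero-fat birds, which this
    package does not refit.
    """

    coefficients: dict[str, tuple[float, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = {"F", "M"} - set(self.coefficients)
        if missing:
            raise ValueError(f"fat-free model missing sexes: {sorted(missing)}")
        for sex, (a, b) in self.coefficients.items():
            if not (abs(a) < 1e6 and abs(b) < 1e6):
                raise ValueError(f"non-finite coefficients for sex {sex!r}")


def fat_free_mass(
    wing_chord_mm: float,
    sex: str,
    model: FatFreeModel,
    chord_window: tuple[float, float] = DEFAULT_CHORD_WINDOW,
) -> float:
    """Predicted fat-free body mass (g) for one bird.

    A wing chord outside the plausibility window triggers a warning but
    the value is still computed (the regression extrapolates linearly).
    """
    if sex not in model.coefficients:
        raise ValueError(f"unknown sex code {sex!r}; expected one of "
                         f"{sorted(model.coefficients)}")
    lo, hi = chord_window
    if not (lo <= wing_chord_mm <= hi):
        warnings.warn(
            f"wing chord {wing_chord_mm} mm outside plausibility window "
            f"[{lo}, {hi}] mm; extrapolating",
            stacklevel=2,
        )
    intercept, slope = model.coefficients[sex]
    return intercept + slope * wing_chord_mm


def fuel_load(mass_g: float, fat_free_mass_g: float) -> float:
    """Capture mass minus fat-free mass (g).

    May be negative under measurement noise; negative values are logged
    but never clamped, so downstream models stay unbiased.
    """
    load = mass_g - fat_free_mass_g
    if load < 0:
        logger.info("negative fuel load %.3f g (mass %.3f, fat-free %.3f)",
                    load, mass_g, fat_free_mass_g)
    return load


def ordinal_day(date: _dt.date | str) -> int:
    """Day of year (Jan 1 = 1), leap-aware.

    Accepts a :class:`datetime.date` or an ISO ``YYYY-MM-DD`` string.
    """
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValueError(f"invalid date {date!r}") from exc
    return date.timetuple().tm_yday
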