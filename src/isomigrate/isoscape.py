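"""Multiple-linear-regression precipitation δ²H isoscape.

The growing-season precipitation δ²H surface is modelled as an ordinary
least-squares function of gridded covariates (temperature, elevation,
latitude, longitude by default).  The fitted model predicts a mean
surface and a design-based prediction standard-error surface used
downstream when the isoscape is rescaled to feather values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .raster import AlignmentError, RangeMask, RasterGrid

__all__ = [
    "IsoscapeModel",
    "fit_isoscape",
    "predict_isoscape",
    "extract_at_sites",
]


@dataclass
class IsoscapeModel:
    """OLS fit of precipitation δ²H on covariate grids.

    ``coefficients[0]`` is the intercept (‰); the remaining entries are
    one slope per covariate in the order the covariates were supplied.
    ``xtx_inv`` (the unscaled parameter covariance factor (XᵀX)⁻¹) is
    retained so prediction standard errors can be computed cellwise.
    """

    coefficients: np.ndarray
    coefficient_ses: np.ndarray
    residual_sd: float
    n_cells_fit: int
    r_squared: float
    covariate_names: tuple[str, ...]
    xtx_inv: np.ndarray

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if len(self.coefficients) != len(self.covariate_names) + 1:
            raise ValueError("one slope required per covariate plus intercept")

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    # -- plain-text serialization ----------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_cells_fit {self.n_cells_fit}\n")
            fh.write(f"residual_sd {self.residual_sd!r}\n")
            fh.write(f"r_squared {self.r_squared!r}\n")
            fh.write(f"covariates {','.join(self.covariate_names)}\n")
            fh.write("coefficients " +
                     " ".join(repr(float(c)) for c in self.coefficients) + "\n")
            fh.write("coefficient_ses " +
                     " ".join(repr(float(c)) for c in self.coefficient_ses) + "\n")
            fh.write("xtx_inv " +
                     " ".join(repr(float(v)) for v in self.xtx_inv.ravel()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "IsoscapeModel":
        fields: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                key, _, rest = line.partition(" ")
                fields[key] = rest.strip()
        names = tuple(n for n in fields["covariates"].split(",") if n)
        p = len(names) + 1
        return cls(
            coefficients=np.array([float(v) for v in fields["coefficients"].split()]),
            coefficient_ses=np.array(
                [float(v) for v in fields["coefficient_ses"].split()]),
            residual_sd=float(fields["residual_sd"]),
            n_cells_fit=int(fields["n_cells_fit"]),
            r_squared=float(fields["r_squared"]),
            covariate_names=names,
            xtx_inv=np.array(
                [float(v) for v in fields["xtx_inv"].split()]).reshape(p, p),
        )


def _stack_valid(
    grids: Sequence[RasterGrid],
    extra_invalid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design rows for cells valid in every grid; returns (X, valid)."""
    ref = grids[0]
    valid = ref.valid_mask()
    for g in grids[1:]:
        ref.require_aligned(g, "covariate grid")
        valid &= g.valid_mask()
    if extra_invalid is not None:
        valid &= ~extra_invalid
    X = np.column_stack([g.values[valid] for g in grids])
    return X, valid


def fit_isoscape(
    precip_d2h: RasterGrid,
    covariates: Sequence[RasterGrid],
    mask: RangeMask | None = None,
    covariate_names: Sequence[str] | None = None,
) -> IsoscapeModel:
    """Fit the OLS isoscape over valid (optionally range-masked) cells.

    Raises a singular-design error naming collinear covariates when the
    design matrix is rank deficient.
    """
    if covariate_names is None:
        covariate_names = tuple(f"covariate_{i}" for i in range(len(covariates)))
    if len(covariate_names) != len(covariates):
        raise ValueError("one name per covariate grid required")
    if mask is not None:
        precip_d2h.require_aligned(mask.grid, "range mask")
    X, valid = _stack_valid([precip_d2h, *covariates],
                            None if mask is None else ~mask.inside())
    y, X = X[:, 0], X[:, 1:]
    p = X.shape[1]
    if y.size < p + 1:
        raise ValueError(f"need at least {p + 1} valid cells, have {y.size}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which covariates are collinear with the rest
        culprits = []
        for j in range(p):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                culprits.append(covariate_names[j])
        raise np.linalg.LinAlgError(
            f"singular design: collinear covariates {culprits or list(covariate_names)}"
        )
    fit = sm.OLS(y, design).fit()
    # floor the residual dof at 1 so a saturated fit (zero residuals)
    # yields zero rather than undefined uncertainty
    resid_dof = max(y.size - design.shape[1], 1)
    residual_sd = float(np.sqrt(fit.ssr / resid_dof))
    r2 = float(np.clip(fit.rsquared if y.size > design.shape[1] else 1.0, 0.0, 1.0))
    xtx_inv = np.linalg.inv(design.T @ design)
    return IsoscapeModel(
        coefficients=np.asarray(fit.params),
        coefficient_ses=residual_sd * np.sqrt(np.diag(xtx_inv)),
        residual_sd=residual_sd,
        n_cells_fit=int(y.size),
        r_squared=r2,
        covariate_names=tuple(covariate_names),
        xtx_inv=xtx_inv,
    )


def predict_isoscape(
    model: IsoscapeModel,
    covariates: Sequence[RasterGrid],
) -> tuple[RasterGrid, RasterGrid]:
    """Cellwise mean prediction and design-based prediction SE.

    The SE surface is the standard error of the fitted mean,
    ``residual_sd * sqrt(xᵀ(XᵀX)⁻¹x)``; it is minimal at the covariate
    mean of the training cells.  Nodata in any covariate propagates to
    both outputs.
    """
    if len(covariates) != model.n_covariates:
        raise ValueError(
            f"model expects {model.n_covariates} covariates, got {len(covariates)}"
        )
    ref = covariates[0]
    X, valid = _stack_valid(list(covariates))
    design = np.column_stack([np.ones(X.shape[0]), X])
    mean = design @ model.coefficients
    # diag(D (X'X)^-1 D') without forming the full matrix
    se = model.residual_sd * np.sqrt(
        np.einsum("ij,jk,ik->i", design, model.xtx_inv, design)
    )
    mean_out = np.full(ref.shape, ref.nodata_value)
    se_out = np.full(ref.shape, ref.nodata_value)
    mean_out[valid] = mean
    se_out[valid] = se
    return ref.with_values(mean_out), ref.with_values(se_out)


def extract_at_sites(
    surface: RasterGrid,
    sites: Sequence[tuple[float, float]],
) -> list[float]:
    """Containing-cell values at (lon, lat) points — no interpolation.

    All offending sites (outside the extent or on nodata cells) are
    collected and reported together.
    """
    values: list[float] = []
    bad: list[tuple[int, str]] = []
    for i, (lon, lat) in enumerate(sites):
        try:
            row, col = surface.index_of(lon, lat)
        except IndexError:
            bad.append((i, f"({lon}, {lat}) outside grid extent"))
            continue
        v = surface.values[row, col]
        if v == surface.nodata_value:
            bad.append((i, f"({lon}, {lat}) falls on a nodata cell"))
            continue
        values.append(float(v))
    if bad:
        detail = "; ".join(f"site {i}: {msg}" for i, msg in bad)
        raise ValueError(f"invalid site locations — {detail}")
    return values
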