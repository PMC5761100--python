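"""Additive mixed model of natal latitude on arrival phenology.

The stage that classifies the temporal migration pattern: predicted
natal latitude (the per-bird assignment centroid) is regressed on
smooth functions of arrival ordinal day, fat-free body mass and fuel
load, with a random intercept per capture year.  A type 1 pattern
(southern populations migrate first) shows up as a significant
positive arrival-day effect — birds captured later come from higher
latitudes; a significant negative effect would indicate type 2.

Smooth terms are B-spline bases of modest dimension (default 5) fit as
fixed effects inside a linear mixed model; each term is tested with a
Wald F test on its coefficient block.  The direction of a smooth is
the sign of the slope of an ordinary least-squares line through the
fitted partial effect over the observed predictor range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

__all__ = [
    "TermResult",
    "TemporalFit",
    "screen_predictors",
    "fit_latitude_model",
    "classify_pattern",
    "plot_arrival_latitude",
]

logger = logging.getLogger(__name__)

PREDICTORS = ("ordinal_day", "fat_free_mass_g", "fuel_load_g")
DEFAULT_BASIS_DF = 5
DEFAULT_ALPHA = 0.05
#: smooth range (response units) below which a term is called flat
FLAT_TOL = 1e-8


@dataclass
class TermResult:
    """Per-term test: Wald F on the term's spline coefficient block."""

    name: str
    edf: float          # columns spent on the term's basis
    f_stat: float
    p_value: float
    direction: str      # positive | negative | flat
    smooth_x: np.ndarray = field(repr=False, default=None)
    smooth_y: np.ndarray = field(repr=False, default=None)


@dataclass
class TemporalFit:
    """Fitted additive mixed model and its per-term summaries."""

    terms: dict[str, TermResult]
    year_variance: float      # random-intercept variance, degrees²
    n: int
    n_years: int
    mixed: bool               # False when the fixed-effects fallback ran
    alpha: float = DEFAULT_ALPHA

    @property
    def arrival(self) -> TermResult:
        return self.terms["ordinal_day"]

    @property
    def direction_of_arrival_effect(self) -> str:
        return self.arrival.direction

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_years": self.n_years,
            "mixed": self.mixed,
            "alpha": self.alpha,
            "year_variance": self.year_variance,
            "terms": {
                name: {
                    "edf": t.edf,
                    "f_stat": t.f_stat,
                    "p_value": t.p_value,
                    "direction": t.direction,
                }
                for name, t in self.terms.items()
            },
        }


def screen_predictors(
    migrants: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    warn_threshold: float = 0.7,
) -> pd.DataFrame:
    """Pairwise Spearman correlations among the candidate predictors.

    Collinear predictors (|rho| above the threshold) are logged as a
    warning; constant predictors yield NaN for their pairs.
    """
    df = migrants[list(predictors)].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete cases")
    k = len(predictors)
    out = pd.DataFrame(np.eye(k), index=predictors, columns=predictors)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = df.iloc[:, i], df.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                rho = np.nan
                logger.warning("constant predictor in pair (%s, %s); "
                               "Spearman rho undefined",
                               predictors[i], predictors[j])
            else:
                rho = stats.spearmanr(xi, xj).statistic
                if abs(rho) > warn_threshold:
                    logger.warning("predictors %s and %s correlated "
                                   "(rho=%.3f)", predictors[i],
                                   predictors[j], rho)
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def _partial_effect(
    design_info,
    beta: np.ndarray,
    term_name: str,
    var: str,
    data: pd.DataFrame,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted smooth for one term over the observed predictor range."""
    xs = np.linspace(data[var].min(), data[var].max(), n_grid)
    frame = pd.DataFrame({
        v: (xs if v == var else np.full(n_grid, data[v].median()))
        for v in data.columns
    })
    (X,) = patsy.build_design_matrices([design_info], frame)
    X = np.asarray(X)
    sl = design_info.term_name_slices[term_name]
    ys = X[:, sl] @ beta[sl]
    return xs, ys


def _direction(xs: np.ndarray, ys: np.ndarray) -> str:
    if np.ptp(ys) < FLAT_TOL:
        return "flat"
    slope = np.polyfit(xs, ys, 1)[0]
    if slope > 0:
        return "positive"
    if slope < 0:
        return "negative"
    return "flat"


def fit_latitude_model(
    migrants: pd.DataFrame,
    response: str = "centroid_lat",
    predictors: Sequence[str] = PREDICTORS,
    basis_df: int = DEFAULT_BASIS_DF,
    alpha: float = DEFAULT_ALPHA,
    min_mixed_n: int = 20,
) -> TemporalFit:
    """Fit the additive mixed model of predicted natal latitude.

    Complete cases only; birds with missing fields are dropped with
    their ids logged.  When fewer than ``min_mixed_n`` complete cases
    or fewer than two years are available, a fixed-effects-only fit
    runs instead (logged).  A singular fit is retried once with basis
    dimension 3 before raising.
    """
    import statsmodels.formula.api as smf

    cols = [response, *predictors, "year"]
    df = migrants[cols + (["bird_id"] if "bird_id" in migrants else [])].copy()
    incomplete = df[df[cols].isna().any(axis=1)]
    if len(incomplete) and "bird_id" in incomplete:
        logger.warning("dropping incomplete cases: %s",
                       sorted(incomplete["bird_id"].astype(str)))
    df = df.dropna(subset=cols).reset_index(drop=True)
    n = len(df)
    if n < len(predictors) * 2 + 2:
        raise ValueError(f"too few complete cases ({n}) for the model")
    n_years = df["year"].nunique()

    y = df[response].to_numpy(dtype=float)
    if np.ptp(y) < 1e-12:
        # constant response: nothing to model
        terms = {
            p: TermResult(name=p, edf=0.0, f_stat=0.0, p_value=1.0,
                          direction="flat",
                          smooth_x=np.array([]), smooth_y=np.array([]))
            for p in predictors
        }
        return TemporalFit(terms=terms, year_variance=0.0, n=n,
                           n_years=n_years, mixed=False, alpha=alpha)

    use_mixed = n >= min_mixed_n and n_years >= 2
    if not use_mixed:
        logger.info("falling back to fixed-effects-only fit "
                    "(n=%d, years=%d)", n, n_years)

    def _try_fit(bdf):
        formula = f"{response} ~ " + " + ".join(
            f"bs({p}, df={bdf})" for p in predictors
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if not use_mixed:
                model = smf.ols(formula, df)
                return model, model.fit(), 0.0
            last_exc = None
            # gradient-free optimizers survive near-singular REML
            # profiles that defeat lbfgs when the year variance is ~0
            for method in ("lbfgs", "powell", "nm"):
                model = smf.mixedlm(formula, df, groups=df["year"])
                try:
                    result = model.fit(reml=True, method=[method])
                    return model, result, float(result.cov_re.iloc[0, 0])
                except (np.linalg.LinAlgError, ValueError) as exc:
                    last_exc = exc
            raise last_exc

    try:
        model, result, year_var = _try_fit(basis_df)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("singular fit at basis df=%d; retrying with 3",
                       basis_df)
        try:
            model, result, year_var = _try_fit(3)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise RuntimeError(f"model is singular even at basis "
                               f"dimension 3: {exc}") from exc

    design_info = model.data.design_info
    beta_names = list(model.exog_names)
    beta = np.asarray(result.params)[: len(beta_names)]
    n_params = len(result.params)
    resid_dof = max(n - len(beta_names), 1)

    data_cols = df[list(predictors)]
    terms: dict[str, TermResult] = {}
    for p in predictors:
        term_name = next(t for t in design_info.term_names if f"bs({p}," in t)
        sl = design_info.term_name_slices[term_name]
        k = sl.stop - sl.start
        R = np.zeros((k, n_params))
        for i, j in enumerate(range(sl.start, sl.stop)):
            R[i, j] = 1.0
        wt = result.wald_test(R, scalar=True)
        chi2 = float(np.squeeze(wt.statistic))
        f_stat = chi2 / k
        p_value = float(stats.f.sf(f_stat, k, resid_dof))
        xs, ys = _partial_effect(design_info, beta, term_name, p, data_cols)
        terms[p] = TermResult(
            name=p, edf=float(k), f_stat=f_stat, p_value=p_value,
            direction=_direction(xs, ys), smooth_x=xs, smooth_y=ys,
        )

    return TemporalFit(terms=terms, year_variance=year_var, n=n,
                       n_years=n_years, mixed=use_mixed, alpha=alpha)


def classify_pattern(fit: TemporalFit, alpha: float | None = None) -> str:
    """Classify the temporal migration pattern from the fitted model.

    ``type_1`` — the arrival-day effect on natal latitude is
    significant and positive (southern populations pass first);
    ``type_2`` — significant and negative; ``indeterminate`` otherwise.
    """
    alpha = fit.alpha if alpha is None else alpha
    arrival = fit.arrival
    if arrival.p_value < alpha and arrival.direction == "positive":
        return "type_1"
    if arrival.p_value < alpha and arrival.direction == "negative":
        return "type_2"
    return "indeterminate"


def plot_arrival_latitude(
    migrants: pd.DataFrame,
    path,
    response: str = "centroid_lat",
    frac: float = 0.6,
    n_boot: int = 200,
    seed: int = 0,
):
    """Diagnostic plot: predicted natal latitude vs arrival day.

    A locally weighted (loess-style) regression line with a bootstrap
    95% confidence band, one panel for all years pooled.  Separate
    from inference; purely descriptive.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from statsmodels.nonparametric.smoothers_lowess import lowess

    df = migrants.dropna(subset=["ordinal_day", response])
    x = df["ordinal_day"].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), 100)
    fit = lowess(y, x, frac=frac, xvals=grid)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        boots[b] = lowess(y[idx], x[idx], frac=frac, xvals=grid)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=12, alpha=0.5, color="#2a6f97", label="birds")
    ax.plot(grid, fit, color="#d1495b", label="loess")
    ax.fill_between(grid, lo, hi, color="#d1495b", alpha=0.2, label="95% CI")
    ax.set_xlabel("arrival ordinal day")
    ax.set_ylabel("predicted natal latitude (°N)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
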