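"""Does carnivore habitat use track the ungulate birth pulse?

Weekly mean parturition-RSF scores at each carnivore's GPS fixes (15 April
to 31 July) are the response of a linear mixed model with a random intercept
per animal and Julian week — linear, or linear + quadratic — as fixed
effects, fitted by maximum likelihood so a likelihood-ratio test between
the nested forms is valid.  A supported concave quadratic whose vertex sits
at the birth-pulse peak is the signature of a predator shifting its habitat
use to maximize encounters with neonates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .rasters import RasterStack

__all__ = [
    "julian_week",
    "weekly_use",
    "PhenologyFit",
    "fit_phenology",
    "LRTResult",
    "lrt",
    "peak_week",
]


def julian_week(t: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Weeks since 1 January: week 1 = days 1-7 (ceil of day-of-year / 7)."""
    doy = pd.DatetimeIndex(t).dayofyear.to_numpy()
    return np.ceil(doy / 7.0).astype(int)


def weekly_use(
    predator_fixes: pd.DataFrame,
    surface: RasterStack,
    start_md: str = "04-15",
    end_md: str = "07-31",
    layer: str = "rsf_score",
    min_fixes: int = 1,
    rescale: bool = False,
) -> pd.DataFrame:
    """Per animal x Julian week mean RSF score over fixes in the window.

    Weeks partially outside 15 Apr-31 Jul are truncated to the fixes inside;
    fixes on missing surface cells are dropped (count returned in the
    ``n_dropped`` attribute of the result's ``attrs``).  Means are unweighted
    across the week's fixes.  Raw w(x) scores are used by default;
    ``rescale=True`` min-max rescales the surface to [0, 1] first, which
    only changes the response's scale, not the phenology inference.
    """
    t = pd.DatetimeIndex(predator_fixes["t"])
    m_start = tuple(int(v) for v in start_md.split("-"))
    m_end = tuple(int(v) for v in end_md.split("-"))
    md = list(zip(t.month, t.day))
    in_win = np.array([(m_start <= pair <= m_end) for pair in md])
    df = predator_fixes[in_win].copy()
    if len(df) == 0:
        import warnings

        warnings.warn("no fixes inside the seasonal window", stacklevel=2)
        out = pd.DataFrame(columns=["animal_id", "year", "week", "mean_score", "n_fixes"])
        out.attrs["n_dropped"] = 0
        return out
    score = surface.sample(df["x"].to_numpy(), df["y"].to_numpy(), layer)
    if rescale:
        arr = surface.layers[layer]
        lo, hi = np.nanmin(arr), np.nanmax(arr)
        score = (score - lo) / (hi - lo) if hi > lo else np.zeros_like(score)
    df["score"] = score
    n_dropped = int(np.isnan(score).sum())
    df = df[np.isfinite(df["score"])]
    tt = pd.DatetimeIndex(df["t"])
    df["year"] = tt.year
    df["week"] = julian_week(tt)
    grouped = (
        df.groupby(["animal_id", "year", "week"])
        .agg(mean_score=("score", "mean"), n_fixes=("score", "size"))
        .reset_index()
    )
    grouped = grouped[grouped["n_fixes"] >= min_fixes].reset_index(drop=True)
    grouped.attrs["n_dropped"] = n_dropped
    return grouped


@dataclass
class PhenologyFit:
    """Random-intercept LMM of weekly use on (centered, scaled) Julian week."""

    form: str  # "linear" | "quadratic"
    fe_names: list[str]
    fe: np.ndarray
    fe_se: np.ndarray
    re_var: float
    resid_var: float
    loglik: float
    n_animals: int
    n_records: int
    week_center: float
    week_scale: float
    singular: bool = False
    converged: bool = True

    def coef(self, name: str) -> float:
        return float(self.fe[self.fe_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.fe_se[self.fe_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "fixed_effects": [
                {"name": n, "estimate": float(b), "se": float(s)}
                for n, b, s in zip(self.fe_names, self.fe, self.fe_se)
            ],
            "random_intercept_var": self.re_var,
            "residual_var": self.resid_var,
            "loglik": self.loglik,
            "n_animals": self.n_animals,
            "n_records": self.n_records,
            "week_center": self.week_center,
            "week_scale": self.week_scale,
            "singular": self.singular,
            "converged": self.converged,
        }


def fit_phenology(
    records: pd.DataFrame,
    form: Literal["linear", "quadratic"] = "quadratic",
    reml: bool = False,
) -> PhenologyFit:
    """Fit the weekly-use mixed model by ML (default) or REML.

    Week is centered at the midpoint of its observed range and scaled to
    unit standard deviation before squaring (quadratic form), which keeps
    the linear and quadratic terms nearly orthogonal.  The default is
    maximum likelihood so likelihood-ratio tests on the fixed effects are
    valid; ``reml=True`` is for variance reporting only and must not feed
    :func:`lrt`.  A random-intercept variance estimated at (or collapsing
    to) zero is flagged ``singular`` and the model degenerates gracefully
    to ordinary least squares.
    """
    if records["animal_id"].nunique() < 2:
        raise ValueError("need >= 2 animals for a random-intercept model")
    if records["week"].nunique() < 3:
        raise ValueError("need >= 3 distinct weeks")
    week = records["week"].to_numpy(dtype=float)
    center = (week.min() + week.max()) / 2.0
    scale = week.std() if week.std() > 0 else 1.0
    wc = (week - center) / scale
    ycol = "mean_score" if "mean_score" in records.columns else "y"
    yv = records[ycol].to_numpy(dtype=float)

    cols = {"intercept": np.ones_like(wc), "week": wc}
    if form == "quadratic":
        cols["week2"] = wc**2
    elif form != "linear":
        raise ValueError("form must be 'linear' or 'quadratic'")
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    groups = records["animal_id"].to_numpy()

    singular = False
    converged = True
    if np.ptp(yv) == 0:
        # degenerate: constant response, variances 0
        fe = np.zeros(X.shape[1])
        fe[0] = yv[0]
        return PhenologyFit(
            form=form,
            fe_names=names,
            fe=fe,
            fe_se=np.zeros(X.shape[1]),
            re_var=0.0,
            resid_var=0.0,
            loglik=float("inf"),
            n_animals=int(records["animal_id"].nunique()),
            n_records=len(records),
            week_center=center,
            week_scale=scale,
            singular=True,
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(yv, X, groups=groups)
        try:
            # ML surfaces near the variance boundary are awkward for any one
            # optimizer; take the best of several so nested fits stay nested
            res = None
            for method in ("lbfgs", "bfgs", "powell", "cg"):
                try:
                    cand = model.fit(reml=reml, method=method, maxiter=1000)
                except Exception:
                    continue
                if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf):
                    res = cand
            if res is None:
                raise RuntimeError("all optimizers failed")
            converged = bool(res.converged)
            re_var = float(np.asarray(res.cov_re).ravel()[0])
            if re_var < 1e-10:
                singular = True
            fe = np.asarray(res.fe_params)
            fe_se = np.asarray(res.bse_fe)
            resid_var = float(res.scale)
            llf = float(res.llf)
        except Exception:
            # boundary failure: random effect collapses, fall back to OLS
            singular = True
            ols = sm.OLS(yv, X).fit()
            fe = np.asarray(ols.params)
            fe_se = np.asarray(ols.bse)
            re_var = 0.0
            resid_var = float(ols.scale)
            llf = float(ols.llf)
    return PhenologyFit(
        form=form,
        fe_names=names,
        fe=fe,
        fe_se=fe_se,
        re_var=re_var,
        resid_var=resid_var,
        loglik=llf,
        n_animals=int(records["animal_id"].nunique()),
        n_records=len(records),
        week_center=center,
        week_scale=scale,
        singular=singular,
        converged=converged,
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p": self.p}


def lrt(full: PhenologyFit, reduced: PhenologyFit, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of nested ML fits (quadratic vs linear: df=1)."""
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -tol:
        raise ValueError(
            f"reduced logLik exceeds full by {-stat / 2:.3g}: fit problem, not a test result"
        )
    stat = max(stat, 0.0)
    df = len(full.fe_names) - len(reduced.fe_names)
    if df < 1:
        df = 1
    return LRTResult(statistic=float(stat), df=df, p=float(stats.chi2.sf(stat, df)))


def peak_week(fit: PhenologyFit) -> float:
    """Julian week at which the fitted quadratic is maximized.

    The vertex -b/(2a) on the centered/scaled week axis, back-transformed to
    the original week scale.  Requires a concave quadratic (a < 0).
    """
    if "week2" not in fit.fe_names:
        raise ValueError("peak_week requires a quadratic fit")
    a = fit.coef("week2")
    b = fit.coef("week")
    if a >= 0:
        raise ValueError("quadratic coefficient is non-negative: no interior maximum")
    zc = -b / (2.0 * a)
    return float(zc * fit.week_scale + fit.week_center)
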