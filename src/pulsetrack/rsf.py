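"""Parturition-habitat resource selection function (RSF) for elk.

Used points are adult-female fixes in the 7 days immediately following a
parturition event; availability is 10 uniform random points per used point
over the entire area used by elk (its fix MCP by default).  A binomial GLM
with logit link on the full 10-covariate design — no model selection — gives
the selection coefficients, and w(x) = exp(beta' x_std), without intercept,
projected per 30-m cell is the parturition-habitat score surface the
phenology analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import MultiPoint, Point
from shapely.prepared import prep

from .rasters import RasterStack
from .telemetry_io import Standardization, sample_covariates

__all__ = [
    "RSF_CONTINUOUS",
    "RSFFit",
    "postpartum_used_points",
    "elk_range_polygon",
    "draw_available",
    "build_rsf_design",
    "fit_rsf",
    "predict_surface",
]

VEG_DUMMIES = ["veg_closed_forest", "veg_grassland", "veg_other"]

RSF_CONTINUOUS = [
    "canopy",
    "ln_dist_road",
    "ln_dist_water",
    "ruggedness",
    "shrub",
    "forb",
    "slope",
    "elevation",
]


@dataclass
class RSFFit:
    """Fitted RSF: named coefficients, SEs, standardization, settings."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    standardization: Standardization
    availability_ratio: float
    aspect_mode: str
    n_used: int
    n_available: int
    converged: bool
    message: str = ""
    dropped: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {"name": n, "estimate": float(b), "se": float(s), "z": float(zz), "p": float(pp)}
                for n, b, s, zz, pp in zip(self.names, self.beta, self.se, self.z, self.p)
            ],
            "loglik": self.loglik,
            "n_used": self.n_used,
            "n_available": self.n_available,
            "availability_ratio": self.availability_ratio,
            "aspect_mode": self.aspect_mode,
            "converged": self.converged,
            "dropped": list(self.dropped),
        }


def postpartum_used_points(
    prey_fixes: pd.DataFrame, events: pd.DataFrame, days: float = 7.0
) -> pd.DataFrame:
    """All fixes within ``days`` after each animal's parturition event."""
    window = pd.Timedelta(days=days)
    out = []
    for row in events.itertuples():
        grp = prey_fixes[prey_fixes["animal_id"] == row.animal_id]
        t0 = pd.Timestamp(row.event_time)
        seg = grp[(grp["t"] >= t0) & (grp["t"] <= t0 + window)]
        out.append(seg[["animal_id", "t", "x", "y"]])
    if not out:
        return pd.DataFrame(columns=["animal_id", "t", "x", "y"])
    return pd.concat(out, ignore_index=True)


def elk_range_polygon(prey_fixes: pd.DataFrame):
    """MCP (convex hull) of all prey fixes: the 'entire area used' polygon."""
    pts = MultiPoint(list(zip(prey_fixes["x"], prey_fixes["y"])))
    return pts.convex_hull


def draw_available(polygon, n_used: int, ratio: float = 10.0, seed: int = 0) -> pd.DataFrame:
    """``n_used * ratio`` points uniform over the polygon (with replacement).

    Rejection sampling from the bounding box; duplicated cells are allowed.
    """
    if polygon.area <= 0:
        raise ValueError("availability polygon has zero area")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(n_used * ratio))
    xmin, ymin, xmax, ymax = polygon.bounds
    prepared = prep(polygon)
    xs: list[float] = []
    ys: list[float] = []
    while len(xs) < n:
        m = max(2 * (n - len(xs)), 100)
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        for px, py in zip(cx, cy):
            if prepared.contains(Point(px, py)):
                xs.append(px)
                ys.append(py)
                if len(xs) == n:
                    break
    return pd.DataFrame({"x": xs, "y": ys})


def _rsf_columns(cov: pd.DataFrame, aspect_mode: str) -> pd.DataFrame:
    out = pd.DataFrame(index=cov.index)
    out["canopy"] = cov["canopy"]
    out["ln_dist_road"] = np.log1p(cov["dist_road"])
    out["ln_dist_water"] = np.log1p(cov["dist_water"])
    out["ruggedness"] = cov["ruggedness"]
    out["shrub"] = cov["shrub"]
    out["forb"] = cov["forb"]
    out["slope"] = cov["slope"]
    if aspect_mode == "sincos":
        rad = np.deg2rad(cov["aspect"])
        out["aspect_sin"] = np.sin(rad)
        out["aspect_cos"] = np.cos(rad)
    elif aspect_mode == "degrees":
        out["aspect"] = cov["aspect"]
    else:
        raise ValueError("aspect_mode must be 'sincos' or 'degrees'")
    out["elevation"] = cov["elevation"]
    veg = cov["veg_class"].to_numpy()
    out["veg_closed_forest"] = (veg == 1).astype(float)
    out["veg_grassland"] = (veg == 2).astype(float)
    out["veg_other"] = (veg == 3).astype(float)
    return out


def build_rsf_design(
    used: pd.DataFrame,
    available: pd.DataFrame,
    landscape: RasterStack,
    aspect_mode: str = "sincos",
) -> tuple[pd.DataFrame, np.ndarray, list[str], Standardization]:
    """Pooled used+available design with standardized continuous covariates.

    Aspect, a circular covariate, defaults to a sin/cos pair; the
    ``degrees`` mode keeps it as a single raw-degree column.  Returns
    (design, labels, covariate names, standardization).
    """
    pts = pd.concat([used[["x", "y"]], available[["x", "y"]]], ignore_index=True)
    labels = np.concatenate([np.ones(len(used)), np.zeros(len(available))])
    cov = sample_covariates(pts, landscape)
    ok = cov["in_bounds"].to_numpy()
    design = _rsf_columns(cov, aspect_mode)
    design = design[ok].reset_index(drop=True)
    labels = labels[ok]
    continuous = [c for c in RSF_CONTINUOUS if c in design.columns]
    if aspect_mode == "degrees":
        continuous = continuous + ["aspect"]
    std = Standardization.fit(design, continuous)
    design = std.apply(design)
    names = list(design.columns)
    return design, labels, names, std


def fit_rsf(
    used: pd.DataFrame,
    available: pd.DataFrame,
    landscape: RasterStack,
    aspect_mode: str = "sincos",
) -> RSFFit:
    """Logistic regression of used (1) vs available (0) on the global model.

    Fitted by IRLS via a binomial GLM with logit link; no variable
    selection.  Complete separation or non-convergence is flagged, not
    silent.
    """
    if len(used) == 0 or len(available) == 0:
        raise ValueError("both used and available points are required")
    design, labels, names, std = build_rsf_design(used, available, landscape, aspect_mode)
    dropped = tuple(std.constant_columns)
    keep = [n for n in names if n not in dropped and design[n].nunique() > 1]
    X = sm.add_constant(design[keep].to_numpy(dtype=float), has_constant="add")
    model = sm.GLM(labels, X, family=sm.families.Binomial())
    converged = True
    message = ""
    try:
        res = model.fit(maxiter=200)
        converged = bool(res.converged)
        if np.max(np.abs(res.params[1:])) > 30:
            converged = False
            message = "diverging coefficients (possible complete separation)"
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"RSF fit failed: {exc}") from exc
    full_names = ["intercept"] + keep
    return RSFFit(
        names=full_names,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        z=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        loglik=float(res.llf),
        standardization=std,
        availability_ratio=len(available) / len(used),
        aspect_mode=aspect_mode,
        n_used=int(labels.sum()),
        n_available=int(len(labels) - labels.sum()),
        converged=converged,
        message=message,
        dropped=dropped,
    )


def predict_surface(fit: RSFFit, landscape: RasterStack) -> RasterStack:
    """Per-cell RSF score w(x) = exp(beta' x_std), intercept excluded.

    The surface uses the fit's own standardization constants; cells with any
    missing covariate are missing in the output.  Returned as a single-layer
    stack named ``rsf_score`` on the landscape's grid.
    """
    if fit.standardization is None:
        raise ValueError("fit carries no standardization constants")
    shape = landscape.shape
    flat = {name: arr.ravel() for name, arr in landscape.layers.items()}
    cov = pd.DataFrame(flat)
    design = _rsf_columns(cov, fit.aspect_mode)
    design = fit.standardization.apply(design)
    lin = np.zeros(len(design))
    for name, b in zip(fit.names, fit.beta):
        if name == "intercept":
            continue
        lin += b * design[name].to_numpy(dtype=float)
    w = np.exp(lin).reshape(shape)
    return RasterStack(
        layers={"rsf_score": w},
        cell_size=landscape.cell_size,
        origin=landscape.origin,
    )
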