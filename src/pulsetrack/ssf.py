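"""Step-selection functions with a parturient-prey encounter covariate.

Each observed predator step is matched with K random steps (default 20)
drawn from Gamma step-length and von Mises turning-angle kernels fitted to
the observed movement.  End-point covariates — the 200-m parturient-prey
encounter indicator, canopy cover, vegetation class, ruggedness, ln distance
to road and water — plus ln(step length) and cos(turning angle) enter a
conditional logistic regression whose strata are the matched sets.  A
positive, significant encounter coefficient means the predator's real steps
ended near parturient females more often than habitat-matched random steps
could explain: evidence of active search rather than incidental encounter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import RasterStack
from .telemetry_io import Standardization, nearest_fix_indices, sample_covariates, times_ns

__all__ = [
    "StepKernels",
    "SelectionFit",
    "StrataDesign",
    "decompose_steps",
    "fit_step_kernels",
    "generate_random_steps",
    "EncounterIndex",
    "encounter_indicator",
    "build_strata",
    "fit_conditional_logistic",
]

SSF_CONTINUOUS = ["canopy", "ruggedness", "ln_dist_road", "ln_dist_water", "ln_step_length"]
VEG_DUMMIES = ["veg_closed_forest", "veg_grassland", "veg_other"]  # ref = open forest


@dataclass
class StepKernels:
    """Fitted movement kernels: Gamma step lengths (m), von Mises turns (rad)."""

    gamma_shape: float
    gamma_scale: float
    vonmises_mu: float
    vonmises_kappa: float

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0 or self.vonmises_kappa <= 0:
            raise ValueError("kernel parameters must be positive")


def decompose_steps(traj: pd.DataFrame) -> pd.DataFrame:
    """Steps (length, bearing, signed turning angle) from one animal's fixes.

    Step ``i`` runs from fix ``i`` to fix ``i+1``; its turning angle is the
    signed difference from the previous step's bearing, wrapped to
    (-pi, pi], counterclockwise positive.  The first step has no previous
    bearing and steps preceded by a zero-length step have an undefined turn;
    both are returned with ``valid=False`` and skipped downstream.
    """
    if len(traj) < 3:
        raise ValueError("need >= 3 fixes to compute turning angles")
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    t = times_ns(traj["t"])
    dx = np.diff(x)
    dy = np.diff(y)
    length = np.hypot(dx, dy)
    bearing = np.arctan2(dy, dx)
    turn = np.full(len(length), np.nan)
    turn[1:] = np.mod(bearing[1:] - bearing[:-1] + np.pi, 2 * np.pi) - np.pi
    turn[turn == -np.pi] = np.pi
    valid = np.ones(len(length), dtype=bool)
    valid[0] = False
    valid[1:] &= length[:-1] > 0  # zero-length previous step: bearing undefined
    valid &= length > 0  # ln(step length) undefined at 0
    return pd.DataFrame(
        {
            "x0": x[:-1],
            "y0": y[:-1],
            "x1": x[1:],
            "y1": y[1:],
            "t_end": t[1:],
            "length": length,
            "bearing": bearing,
            "prev_bearing": np.concatenate([[np.nan], bearing[:-1]]),
            "turn": turn,
            "valid": valid,
        }
    )


def fit_step_kernels(steps: pd.DataFrame) -> StepKernels:
    """Maximum-likelihood Gamma on lengths, von Mises on signed turns."""
    use = steps[steps["valid"]] if "valid" in steps else steps
    lengths = use["length"].to_numpy(dtype=float)
    turns = use["turn"].to_numpy(dtype=float)
    turns = turns[np.isfinite(turns)]
    if len(lengths) < 30:
        raise ValueError("need >= 30 steps to fit movement kernels")
    if np.ptp(lengths) == 0:
        raise ValueError("all step lengths identical; Gamma MLE degenerate — jitter lengths")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    kappa, mu, _ = stats.vonmises.fit(turns, fscale=1)
    return StepKernels(
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        vonmises_mu=float(mu),
        vonmises_kappa=float(max(kappa, 1e-6)),
    )


def generate_random_steps(
    steps: pd.DataFrame, kernels: StepKernels, K: int = 20, seed: int = 0
) -> pd.DataFrame:
    """K random endpoints per valid observed step, anchored at its start fix.

    Random distance ~ fitted Gamma; random heading = previous step's bearing
    plus a von Mises turn — the random locations are projected onto the
    landscape given the previous location, exactly as the observed step was.

    Returns long format: ``step_index, k, x, y, length, turn``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    use = steps[steps["valid"]]
    n = len(use)
    lengths = rng.gamma(kernels.gamma_shape, kernels.gamma_scale, (n, K))
    turns = rng.vonmises(kernels.vonmises_mu, kernels.vonmises_kappa, (n, K))
    heads = use["prev_bearing"].to_numpy()[:, None] + turns
    x = use["x0"].to_numpy()[:, None] + lengths * np.cos(heads)
    y = use["y0"].to_numpy()[:, None] + lengths * np.sin(heads)
    idx = np.repeat(use.index.to_numpy(), K)
    return pd.DataFrame(
        {
            "step_index": idx,
            "k": np.tile(np.arange(K), n),
            "x": x.ravel(),
            "y": y.ravel(),
            "length": lengths.ravel(),
            "turn": turns.ravel(),
        }
    )


class EncounterIndex:
    """Fast 200-m parturient-prey proximity lookups.

    For each prey female with a (detected or known) parturition event, only
    her fixes in the 30 days after the event count; a query point at time t
    scores 1 iff some such female's nearest contemporaneous fix (within the
    matching tolerance, ties to the earlier fix) lies within the radius.
    The radius comparison is inclusive (a prey exactly 200.0 m away counts).
    """

    def __init__(
        self,
        prey_fixes: pd.DataFrame,
        events: pd.DataFrame,
        radius_m: float = 200.0,
        postpartum_window_d: float = 30.0,
        match_tolerance: pd.Timedelta = pd.Timedelta(minutes=15),
    ) -> None:
        if match_tolerance <= pd.Timedelta(0):
            raise ValueError("match tolerance must be positive")
        self.radius_m = float(radius_m)
        self.tol = match_tolerance
        self._prey: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        window = pd.Timedelta(days=postpartum_window_d)
        for row in events.itertuples():
            grp = prey_fixes[prey_fixes["animal_id"] == row.animal_id]
            if len(grp) == 0:
                continue
            t0 = pd.Timestamp(row.event_time)
            seg = grp[(grp["t"] >= t0) & (grp["t"] <= t0 + window)]
            if len(seg) == 0:
                continue
            self._prey.append(
                (
                    times_ns(seg["t"]),
                    seg["x"].to_numpy(dtype=float),
                    seg["y"].to_numpy(dtype=float),
                )
            )

    @classmethod
    def from_pairs(
        cls, parturient_set: list[tuple[pd.DataFrame, pd.Timestamp]], **kwargs
    ) -> "EncounterIndex":
        """Build from (prey trajectory, event time) pairs."""
        fixes = []
        ev_rows = []
        for i, (traj, t_ev) in enumerate(parturient_set):
            traj = traj.copy()
            aid = str(traj["animal_id"].iloc[0]) if "animal_id" in traj else f"prey_{i}"
            traj["animal_id"] = aid
            fixes.append(traj)
            ev_rows.append({"animal_id": aid, "event_time": pd.Timestamp(t_ev)})
        return cls(pd.concat(fixes, ignore_index=True), pd.DataFrame(ev_rows), **kwargs)

    def indicator_at(self, x, y, t_ns) -> np.ndarray:
        """Indicator for many points sharing one query time."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.zeros(len(x), dtype=float)
        tq = np.array([t_ns], dtype="datetime64[ns]")
        r2 = self.radius_m**2
        for tf, px, py in self._prey:
            idx = nearest_fix_indices(tq, tf, self.tol)[0]
            if idx < 0:
                continue
            d2 = (x - px[idx]) ** 2 + (y - py[idx]) ** 2
            out = np.maximum(out, (d2 <= r2).astype(float))
        return out

    def indicator_bulk(self, x, y, t) -> np.ndarray:
        """Indicator for points with per-point query times (vectorized)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t = times_ns(t)
        out = np.zeros(len(x), dtype=float)
        r2 = self.radius_m**2
        for tf, px, py in self._prey:
            idx = nearest_fix_indices(t, tf, self.tol)
            ok = idx >= 0
            if not ok.any():
                continue
            i = np.where(ok, idx, 0)
            d2 = (x - px[i]) ** 2 + (y - py[i]) ** 2
            out = np.maximum(out, (ok & (d2 <= r2)).astype(float))
        return out


def encounter_indicator(
    endpoint: tuple[float, float],
    t: pd.Timestamp,
    parturient_set: list[tuple[pd.DataFrame, pd.Timestamp]],
    radius_m: float = 200.0,
    postpartum_window_d: float = 30.0,
    match_tolerance: pd.Timedelta = pd.Timedelta(minutes=15),
) -> int:
    """1 iff the endpoint is within the radius of a contemporaneous fix of a
    female in the 30 days after her parturition event, else 0."""
    index = EncounterIndex.from_pairs(
        parturient_set,
        radius_m=radius_m,
        postpartum_window_d=postpartum_window_d,
        match_tolerance=match_tolerance,
    )
    val = index.indicator_at(
        np.array([endpoint[0]]), np.array([endpoint[1]]), pd.Timestamp(t).to_datetime64()
    )
    return int(val[0])


@dataclass
class StrataDesign:
    """Long-format matched-set design for the conditional-logistic fit.

    ``table`` has one row per endpoint with ``stratum_id`` (contiguous),
    ``observed`` (exactly one 1 per stratum) and the covariate columns.
    """

    table: pd.DataFrame
    covariates: list[str]
    standardization: Standardization
    n_dropped_strata: int = 0
    n_dropped_endpoints: int = 0
    settings: dict = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return int(self.table["stratum_id"].nunique())


def build_strata(
    predator_fixes: pd.DataFrame,
    landscape: RasterStack,
    prey_fixes: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    kernels: StepKernels | None = None,
    K: int = 20,
    seed: int = 0,
    radius_m: float = 200.0,
    postpartum_window_d: float = 30.0,
    match_tolerance_min: float = 15.0,
    standardize: bool = True,
) -> StrataDesign:
    """Matched strata (1 observed + K random endpoints) with covariates.

    Steps are pooled across the animals present in ``predator_fixes`` (one
    fit per species or species-sex subset: filter the fixes first).  Kernels
    are fitted to the pooled observed steps unless supplied.  Random
    endpoints falling off the raster are dropped; a stratum is dropped when
    its observed endpoint is off-raster or no random endpoint survives.
    Continuous covariates are standardized over the pooled design
    (zero-variance columns flagged and left unscaled); vegetation class is
    expanded to dummies with open forest as the reference; cos(turning
    angle), already bounded in [-1, 1], is left unscaled.
    """
    enc_index = None
    if prey_fixes is not None and events is not None and len(events) > 0:
        enc_index = EncounterIndex(
            prey_fixes,
            events,
            radius_m=radius_m,
            postpartum_window_d=postpartum_window_d,
            match_tolerance=pd.Timedelta(minutes=match_tolerance_min),
        )

    all_steps = []
    for _, grp in predator_fixes.groupby("animal_id", sort=False):
        if len(grp) < 3:
            continue
        all_steps.append(decompose_steps(grp))
    if not all_steps:
        raise ValueError("no usable predator trajectories")
    steps = pd.concat(all_steps, ignore_index=True)
    if kernels is None:
        kernels = fit_step_kernels(steps)

    rand = generate_random_steps(steps, kernels, K=K, seed=seed)
    use = steps[steps["valid"]]

    obs = pd.DataFrame(
        {
            "stratum_id": np.arange(len(use)),
            "observed": 1,
            "x": use["x1"].to_numpy(),
            "y": use["y1"].to_numpy(),
            "t": use["t_end"].to_numpy(),
            "length": use["length"].to_numpy(),
            "turn": use["turn"].to_numpy(),
        }
    )
    sid = pd.Series(np.arange(len(use)), index=use.index)
    rnd = pd.DataFrame(
        {
            "stratum_id": sid.loc[rand["step_index"]].to_numpy(),
            "observed": 0,
            "x": rand["x"].to_numpy(),
            "y": rand["y"].to_numpy(),
            "t": use["t_end"].to_numpy()[
                np.repeat(np.arange(len(use)), K)
            ],
            "length": rand["length"].to_numpy(),
            "turn": rand["turn"].to_numpy(),
        }
    )
    long = pd.concat([obs, rnd], ignore_index=True)

    cov = sample_covariates(long[["x", "y"]], landscape)
    n_endpoints = len(long)
    keep = cov["in_bounds"].to_numpy()
    # drop strata whose observed endpoint is off-raster
    bad_obs = set(long.loc[(long["observed"] == 1) & ~keep, "stratum_id"])
    keep &= ~long["stratum_id"].isin(bad_obs).to_numpy()
    long = long[keep].reset_index(drop=True)
    cov = cov[keep].reset_index(drop=True)
    n_dropped_endpoints = n_endpoints - len(long)

    # strata needing at least one random endpoint
    counts = long.groupby("stratum_id")["observed"].agg(["size", "sum"])
    good = counts[(counts["size"] >= 2) & (counts["sum"] == 1)].index
    n_strata_initial = len(use)
    mask = long["stratum_id"].isin(good).to_numpy()
    long = long[mask].reset_index(drop=True)
    cov = cov[mask].reset_index(drop=True)

    design = pd.DataFrame(
        {
            "stratum_id": pd.factorize(long["stratum_id"], sort=True)[0],
            "observed": long["observed"].to_numpy(),
        }
    )
    if enc_index is not None:
        design["enc"] = enc_index.indicator_bulk(
            long["x"].to_numpy(), long["y"].to_numpy(), long["t"].to_numpy()
        )
    design["canopy"] = cov["canopy"].to_numpy()
    veg = cov["veg_class"].to_numpy()
    design["veg_closed_forest"] = (veg == 1).astype(float)
    design["veg_grassland"] = (veg == 2).astype(float)
    design["veg_other"] = (veg == 3).astype(float)
    design["ruggedness"] = cov["ruggedness"].to_numpy()
    design["ln_dist_road"] = np.log1p(cov["dist_road"].to_numpy())
    design["ln_dist_water"] = np.log1p(cov["dist_water"].to_numpy())
    design["ln_step_length"] = np.log(long["length"].to_numpy())
    design["cos_turn"] = np.cos(long["turn"].to_numpy())
    design["x"] = long["x"].to_numpy()
    design["y"] = long["y"].to_numpy()
    design["t"] = long["t"].to_numpy()

    covariates = (["enc"] if enc_index is not None else []) + [
        "canopy",
        *VEG_DUMMIES,
        "ruggedness",
        "ln_dist_road",
        "ln_dist_water",
        "ln_step_length",
        "cos_turn",
    ]
    std = Standardization.fit(design, SSF_CONTINUOUS)
    if standardize:
        design = std.apply(design)

    design = design.sort_values(["stratum_id", "observed"], ascending=[True, False])
    design = design.reset_index(drop=True)
    return StrataDesign(
        table=design,
        covariates=covariates,
        standardization=std,
        n_dropped_strata=n_strata_initial - design["stratum_id"].nunique(),
        n_dropped_endpoints=n_dropped_endpoints,
        settings={
            "K": K,
            "radius_m": radius_m,
            "postpartum_window_d": postpartum_window_d,
            "match_tolerance_min": match_tolerance_min,
            "kernels": kernels.__dict__,
        },
    )


@dataclass
class SelectionFit:
    """Fitted selection coefficients (SSF or RSF flavor)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    n_strata: int
    converged: bool
    message: str = ""
    dropped: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.p[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {
                    "name": n,
                    "estimate": float(b),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                }
                for n, b, s, z, p in zip(self.names, self.beta, self.se, self.z, self.p)
            ],
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "converged": self.converged,
            "message": self.message,
            "dropped": list(self.dropped),
        }


def _cl_ll_grad_hess(beta, X, y, starts, want_hess=True):
    eta = X @ beta
    # per-stratum logsumexp over contiguous blocks
    seg_max = np.maximum.reduceat(eta, starts)
    n_per = np.diff(np.append(starts, len(eta)))
    row_max = np.repeat(seg_max, n_per)
    e = np.exp(eta - row_max)
    seg_sum = np.add.reduceat(e, starts)
    lse = seg_max + np.log(seg_sum)
    ll = float(eta[y == 1].sum() - lse.sum())
    p_row = e / np.repeat(seg_sum, n_per)
    grad = X[y == 1].sum(axis=0) - p_row @ X
    if not want_hess:
        return ll, grad, None
    Xp = X * p_row[:, None]
    A = X.T @ Xp
    M = np.add.reduceat(Xp, starts, axis=0)  # per-stratum mean vectors
    H = -(A - M.T @ M)
    return ll, grad, H


def fit_conditional_logistic(
    design: StrataDesign | pd.DataFrame,
    covariates: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SelectionFit:
    """Maximize the conditional-logistic likelihood by Newton iteration.

    The likelihood is Sum_strata [beta' x_obs - log Sum_j exp(beta' x_j)].
    Starts at 0; step-halving on likelihood decrease; converged when the
    gradient's max-norm falls below ``tol``.  Standard errors come from the
    inverse observed information.  Covariates constant within every stratum
    are unidentifiable and dropped (recorded in ``dropped``); complete
    separation surfaces as non-convergence with a diagnostic, never
    silently.
    """
    if isinstance(design, StrataDesign):
        df = design.table
        covariates = covariates or design.covariates
    else:
        df = design
        if covariates is None:
            raise ValueError("covariates required with a raw DataFrame")
    df = df.sort_values(["stratum_id", "observed"], ascending=[True, False])
    sid = df["stratum_id"].to_numpy()
    if len(np.unique(sid)) < 2:
        raise ValueError("need >= 2 strata")
    y = df["observed"].to_numpy(dtype=float)

    # drop columns with no within-stratum variation (unidentifiable)
    kept, dropped = [], []
    for c in covariates:
        v = df[c].to_numpy(dtype=float)
        within = pd.Series(v).groupby(sid).transform("mean").to_numpy()
        if np.max(np.abs(v - within)) < 1e-12:
            dropped.append(c)
        else:
            kept.append(c)
    starts = np.concatenate([[0], np.flatnonzero(np.diff(sid)) + 1])
    n_strata = len(starts)
    if not kept:
        # no information about selection: the null (uniform-choice) fit,
        # logLik = -sum log(stratum size)
        sizes = np.diff(np.append(starts, len(sid)))
        return SelectionFit(
            names=[],
            beta=np.empty(0),
            se=np.empty(0),
            z=np.empty(0),
            p=np.empty(0),
            loglik=float(-np.sum(np.log(sizes))),
            n_strata=n_strata,
            converged=True,
            message="all covariates constant within strata; null fit returned",
            dropped=tuple(dropped),
        )
    X = df[kept].to_numpy(dtype=float)

    beta = np.zeros(X.shape[1])
    ll, grad, H = _cl_ll_grad_hess(beta, X, y, starts)
    converged = False
    message = ""
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            message = "singular Hessian (possible separation or collinearity)"
            break
        new_beta = beta + step
        new_ll, new_grad, new_H = _cl_ll_grad_hess(new_beta, X, y, starts)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_H = _cl_ll_grad_hess(new_beta, X, y, starts)
            halvings += 1
        beta, ll, grad, H = new_beta, new_ll, new_grad, new_H
        if np.max(np.abs(beta)) > 15:
            message = "diverging coefficients (complete separation)"
            break
    else:
        message = f"gradient norm {np.max(np.abs(grad)):.2e} > tol at iteration cap"
    if converged and np.max(np.abs(beta)) > 15:
        # likelihood saturates as beta -> inf under separation; a "converged"
        # gradient out there is not an interior optimum
        converged = False
        message = "diverging coefficients (complete separation)"

    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        converged = False
        message = message or "singular information matrix"
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return SelectionFit(
        names=kept,
        beta=beta,
        se=se,
        z=z,
        p=p,
        loglik=ll,
        n_strata=n_strata,
        converged=converged,
        message=message,
        dropped=tuple(dropped),
    )
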