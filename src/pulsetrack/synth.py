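"""Synthetic telemetry with known ground truth.

Three generators mirror the field system the analysis chain is built for:

* :func:`generate_landscape` — co-registered covariate rasters (canopy,
  shrub/forb cover, terrain, vegetation class, distance to roads/water) on a
  30-m grid.
* :func:`simulate_prey` — female ungulates (elk-like 30-min fixes, deer-like
  60–90-min fixes) moving as a correlated random walk until a late-May birth,
  then localizing within a small radius of the birth site for >= 120 h before
  slowly expanding their range again.
* :func:`simulate_predator` — carnivores (2–3-h fixes) whose every step is
  chosen among M candidate endpoints with probability proportional to
  ``exp(beta' x + beta_enc * enc)``, where ``enc`` is the 200-m
  parturient-prey proximity indicator evaluated by the same code the
  step-selection analysis uses.  Setting ``beta_enc > 0`` makes a predator
  that actively searches for neonates; ``beta_enc = 0`` is the incidental-
  encounter null.

All randomness flows from one integer seed per call through
``numpy.random.SeedSequence`` spawning, so runs are bit-reproducible and the
generators can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import RasterStack, distance_layer

__all__ = [
    "LayerSpec",
    "LandscapeConfig",
    "PreyBehaviorConfig",
    "PredatorBehaviorConfig",
    "generate_landscape",
    "simulate_prey",
    "simulate_predator",
    "sample_sites_by_weight",
    "write_true_events",
    "read_true_events",
]

VEG_CLASSES = {0: "open_forest", 1: "closed_forest", 2: "grassland", 3: "other"}


@dataclass
class LayerSpec:
    """Gaussian-random-field parameters for one continuous layer.

    ``scale_m`` is the smoothing length scale in meters; 0 gives spatially
    uncorrelated noise.  Values are clipped to ``clip`` after rescaling.
    """

    mean: float
    sd: float
    scale_m: float = 300.0
    clip: tuple[float | None, float | None] = (None, None)


def _default_layers() -> dict[str, LayerSpec]:
    return {
        "canopy": LayerSpec(40.0, 20.0, 400.0, (0.0, 100.0)),
        "shrub": LayerSpec(20.0, 10.0, 300.0, (0.0, 100.0)),
        "forb": LayerSpec(15.0, 8.0, 300.0, (0.0, 100.0)),
        "ruggedness": LayerSpec(0.15, 0.10, 350.0, (0.0, 1.0)),
        "elevation": LayerSpec(1400.0, 120.0, 900.0, (None, None)),
    }


def _default_veg() -> dict[str, float]:
    return {"open_forest": 0.35, "closed_forest": 0.30, "grassland": 0.25, "other": 0.10}


@dataclass
class LandscapeConfig:
    """Square landscape of ``extent`` x ``extent`` meters at ``cell_size`` m."""

    extent: float = 4000.0
    cell_size: float = 30.0
    layer_params: dict[str, LayerSpec] = field(default_factory=_default_layers)
    veg_proportions: dict[str, float] = field(default_factory=_default_veg)
    veg_scale_m: float = 400.0
    n_roads: int = 2
    n_water: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        total = sum(self.veg_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"vegetation class proportions must sum to 1, got {total}")


def _gaussian_field(shape, spec: LayerSpec, cell_size: float, rng) -> np.ndarray:
    z = rng.standard_normal(shape)
    if spec.scale_m > 0:
        z = ndimage.gaussian_filter(z, sigma=spec.scale_m / cell_size, mode="reflect")
        s = z.std()
        if s > 0:
            z = z / s
    out = spec.mean + spec.sd * z
    lo, hi = spec.clip
    if lo is not None or hi is not None:
        out = np.clip(out, lo, hi)
    return out


def _rasterize_lines(shape, n_lines: int, rng) -> np.ndarray:
    """Mark cells crossed by straight lines spanning the grid."""
    nrows, ncols = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lines):
        # endpoints on opposite grid edges
        if rng.random() < 0.5:
            r0, r1 = 0, nrows - 1
            c0, c1 = rng.integers(0, ncols, 2)
        else:
            c0, c1 = 0, ncols - 1
            r0, r1 = rng.integers(0, nrows, 2)
        n = 2 * max(nrows, ncols)
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        mask[rr, cc] = True
    return mask


def generate_landscape(config: LandscapeConfig) -> RasterStack:
    """One raster layer per covariate used by the SSF and RSF formulas.

    Continuous layers are smoothed Gaussian fields; slope and aspect are
    derived from the elevation field's gradient so the terrain layers are
    mutually consistent; the vegetation layer is categorical with classes
    open forest / closed forest / grassland / other cut from a latent field
    at quantiles matching the configured proportions; distance layers are
    true Euclidean distances to the generated road/water features.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = int(round(config.extent / config.cell_size))
    if n < 2:
        raise ValueError("extent must span at least 2 cells")
    shape = (n, n)
    cs = config.cell_size

    layers: dict[str, np.ndarray] = {}
    for name, spec in config.layer_params.items():
        layers[name] = _gaussian_field(shape, spec, cs, rng)

    elev = layers.get("elevation")
    if elev is None:
        elev = _gaussian_field(shape, LayerSpec(1400.0, 120.0, 900.0), cs, rng)
        layers["elevation"] = elev
    # gradient: rows run north->south, so northward derivative is -d/drow
    g_row, g_col = np.gradient(elev, cs)
    gx, gy = g_col, -g_row
    grade = np.hypot(gx, gy)
    layers["slope"] = np.degrees(np.arctan(grade))
    layers["aspect"] = (np.degrees(np.arctan2(-gx, -gy)) + 360.0) % 360.0

    latent = _gaussian_field(shape, LayerSpec(0.0, 1.0, config.veg_scale_m), cs, rng)
    props = list(config.veg_proportions.values())
    edges = np.quantile(latent, np.cumsum(props)[:-1])
    layers["veg_class"] = np.digitize(latent, edges).astype(float)

    diag = config.extent * np.sqrt(2.0)
    for name, n_feat in (("dist_road", config.n_roads), ("dist_water", config.n_water)):
        if n_feat > 0:
            mask = _rasterize_lines(shape, n_feat, rng)
            layers[name] = distance_layer(mask, cs)
        else:
            layers[name] = np.full(shape, diag)

    return RasterStack(
        layers=layers,
        cell_size=cs,
        origin=(0.0, 0.0),
        categorical={"veg_class"},
        class_labels={"veg_class": dict(VEG_CLASSES)},
    )


# ---------------------------------------------------------------------------
# prey


@dataclass
class PreyBehaviorConfig:
    """Female ungulate movement with a birth pulse and post-partum localization.

    Pre-partum movement is a correlated random walk: step lengths Gamma
    (``step_shape``, ``step_scale_m``), turning angles von Mises
    (``turn_mu``, ``turn_kappa``).  Birth day-of-year is Normal
    (``birth_doy_mean``, ``birth_doy_sd``); elk-like default peaks 27 May.
    From birth, every fix stays within ``localization_radius_m`` of the birth
    site for ``localization_duration_h`` hours (>= 120 h makes the event
    detectable by the rolling-MCP criterion), after which the allowed radius
    grows at ``range_expansion_m_per_h``.
    """

    species: str = "elk"
    sex: str = "F"
    fix_interval_min: float = 30.0
    step_shape: float = 1.2
    step_scale_m: float = 250.0
    turn_mu: float = 0.0
    turn_kappa: float = 0.5
    birth_doy_mean: float = 147.0  # 27 May
    birth_doy_sd: float = 7.0
    localization_radius_m: float = 50.0
    localization_duration_h: float = 144.0
    range_expansion_m_per_h: float = 15.0
    max_postpartum_radius_m: float = 1500.0
    birth_site_beta: dict[str, float] | None = None
    parturient: bool = True

    def __post_init__(self) -> None:
        for name in ("step_shape", "step_scale_m", "turn_kappa", "fix_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.localization_radius_m <= 0:
            raise ValueError("localization_radius_m must be positive")


def sample_sites_by_weight(
    landscape: RasterStack,
    beta: dict[str, float],
    n: int,
    seed: int,
    jitter: bool = True,
) -> pd.DataFrame:
    """Sample ``n`` sites with probability proportional to ``exp(beta' z)``.

    ``z`` are landscape layers standardized over the whole grid, so ``beta``
    is on the per-grid-sd scale.  Returns points at cell centers, uniformly
    jittered within the cell by default.  With ``beta = {}`` sites are
    uniform over the grid.  The exponential weighting is the generative
    counterpart of a resource-selection function.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = landscape.shape
    lin = np.zeros(shape)
    for name, b in beta.items():
        v = landscape.layers[name]
        lin = lin + b * (v - v.mean()) / v.std()
    p = np.exp(lin - lin.max()).ravel()
    p /= p.sum()
    idx = rng.choice(p.size, size=n, p=p)
    row, col = np.unravel_index(idx, shape)
    x, y = landscape.cell_center(row, col)
    if jitter:
        half = landscape.cell_size / 2.0
        x = x + rng.uniform(-half, half, n)
        y = y + rng.uniform(-half, half, n)
    return pd.DataFrame({"x": x, "y": y})


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (handles multiple bounces)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def _crw_positions(n_steps, x0, y0, cfg, rng, lo, hi):
    """Correlated-random-walk positions (n_steps+1 points starting at x0,y0)."""
    lengths = rng.gamma(cfg.step_shape, cfg.step_scale_m, n_steps)
    turns = rng.vonmises(cfg.turn_mu, cfg.turn_kappa, n_steps)
    headings = rng.uniform(-np.pi, np.pi) + np.cumsum(turns)
    dx = lengths * np.cos(headings)
    dy = lengths * np.sin(headings)
    x = _reflect(x0 + np.concatenate([[0.0], np.cumsum(dx)]), lo, hi)
    y = _reflect(y0 + np.concatenate([[0.0], np.cumsum(dy)]), lo, hi)
    return x, y


def simulate_prey(
    config: PreyBehaviorConfig,
    landscape: RasterStack,
    n_animals: int,
    seed: int,
    start: str | pd.Timestamp = "2021-04-15",
    duration_d: float = 90.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate prey trajectories and return (fix table, true events).

    Each animal's trajectory runs backward in time from its birth site (a
    correlated random walk reversed, so the animal arrives at the site
    exactly at its birth time), holds every post-partum fix inside the
    localization radius for the configured duration, then draws fixes from a
    disc whose radius grows at the configured expansion rate — the herd-
    rejoining phase, which real data constrain only loosely.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    xmin, ymin, xmax, ymax = landscape.extent
    r_loc = config.localization_radius_m
    if r_loc >= (xmax - xmin) / 2:
        raise ValueError("localization radius exceeds half the landscape extent")
    ss = np.random.SeedSequence(seed)
    site_seed, traj_ss = ss.spawn(2)

    start = pd.Timestamp(start, tz="UTC")
    end = start + pd.Timedelta(days=duration_d)
    dt = pd.Timedelta(minutes=config.fix_interval_min)
    times = pd.date_range(start, end, freq=dt)
    nt = len(times)

    beta = config.birth_site_beta or {}
    margin = r_loc + landscape.cell_size
    sites = sample_sites_by_weight(landscape, beta, n_animals, site_seed.entropy % (2**31))
    sites["x"] = sites["x"].clip(xmin + margin, xmax - margin)
    sites["y"] = sites["y"].clip(ymin + margin, ymax - margin)

    rows = []
    ev_rows = []
    for i, child in enumerate(traj_ss.spawn(n_animals)):
        rng = np.random.default_rng(child)
        aid = f"{config.species}_{i:03d}"
        sx, sy = float(sites["x"].iloc[i]), float(sites["y"].iloc[i])

        if config.parturient:
            year = start.year
            doy = rng.normal(config.birth_doy_mean, config.birth_doy_sd)
            birth = pd.Timestamp(year, 1, 1, tz="UTC") + pd.Timedelta(
                days=float(doy) - 1 + rng.uniform(0, 1)
            )
            # keep the birth inside the window with room on both sides
            lo_t = start + pd.Timedelta(days=3)
            hi_t = end - pd.Timedelta(hours=config.localization_duration_h + 24)
            birth = min(max(birth, lo_t), hi_t)
            ib = int(np.searchsorted(times.values, birth.to_datetime64()))
        else:
            birth = None
            ib = nt  # whole track is pre-partum-style movement

        # pre-partum: CRW simulated from the site, then reversed
        xpre, ypre = _crw_positions(ib, sx, sy, config, rng, xmin + 1, xmax - 1)
        xs = list(xpre[ib:0:-1])
        ys = list(ypre[ib:0:-1])
        if not config.parturient:
            xs, ys = list(xpre[:nt]), list(ypre[:nt])

        if config.parturient:
            hours = (times[ib:] - birth).total_seconds() / 3600.0
            n_post = len(hours)
            u = rng.uniform(0, 1, n_post)
            ang = rng.uniform(0, 2 * np.pi, n_post)
            r_allow = np.where(
                hours <= config.localization_duration_h,
                r_loc,
                np.minimum(
                    r_loc
                    + config.range_expansion_m_per_h
                    * (hours - config.localization_duration_h),
                    config.max_postpartum_radius_m,
                ),
            )
            rr = r_allow * np.sqrt(u)
            xs.extend(_reflect(sx + rr * np.cos(ang), xmin + 1, xmax - 1))
            ys.extend(_reflect(sy + rr * np.sin(ang), ymin + 1, ymax - 1))

        rows.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "species": config.species,
                    "sex": config.sex,
                    "t": times[: len(xs)],
                    "x": np.asarray(xs, dtype=float),
                    "y": np.asarray(ys, dtype=float),
                }
            )
        )
        if birth is not None:
            ev_rows.append(
                {"animal_id": aid, "event_time": birth, "method": "truth", "x": sx, "y": sy}
            )

    fixes = pd.concat(rows, ignore_index=True)
    events = pd.DataFrame(ev_rows, columns=["animal_id", "event_time", "method", "x", "y"])
    return fixes, events


# ---------------------------------------------------------------------------
# predators


@dataclass
class PredatorBehaviorConfig:
    """Carnivore movement with landscape selection and prey attraction.

    Each step is chosen among ``n_candidates`` endpoints drawn from the
    Gamma step-length / von Mises turning-angle kernels, with selection
    weight ``exp(beta_true' z + beta_enc * enc + w(doy) * s)`` where ``z``
    are grid-standardized landscape layers, ``enc`` the 200-m parturient-prey
    indicator, and ``s`` an optional grid-standardized habitat-suitability
    surface weighted by the day-of-year function ``surface_weight`` (the
    phenology-tracking scenario).  ``n_candidates`` (default 50) is
    deliberately larger than the analysis-side 20 random steps: it controls
    sampler fidelity, not estimation.
    """

    species: str = "cougar"
    sex: str = "M"
    fix_interval_min: float = 180.0
    step_shape: float = 1.3
    step_scale_m: float = 400.0
    turn_mu: float = 0.0
    turn_kappa: float = 0.3
    beta_true: dict[str, float] = field(default_factory=dict)
    beta_enc: float = 0.0
    n_candidates: int = 50
    encounter_radius_m: float = 200.0
    postpartum_window_d: float = 30.0
    match_tolerance_min: float = 15.0
    surface: np.ndarray | None = None
    surface_weight: Callable[[float], float] | None = None
    # range residency: candidate log-weight -strength * (d_home / scale)^2.
    # 0 gives an unconstrained correlated random walk.
    home_range_strength: float = 0.0
    home_range_scale_m: float = 800.0

    def __post_init__(self) -> None:
        for name in ("step_shape", "step_scale_m", "turn_kappa", "fix_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(np.isfinite(list(self.beta_true.values()) or [0.0])):
            raise ValueError("beta_true must be finite")


def simulate_predator(
    config: PredatorBehaviorConfig,
    landscape: RasterStack,
    prey_fixes: pd.DataFrame | None,
    events: pd.DataFrame | None,
    n_animals: int,
    seed: int,
    start: str | pd.Timestamp = "2021-04-15",
    duration_d: float = 90.0,
    return_diagnostics: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate predator trajectories step by step.

    Fix times are offset-jittered per animal so exact-timestamp coincidence
    with prey fixes is rare, exercising the analysis-side nearest-fix
    temporal matching.  With ``return_diagnostics=True`` also returns a table
    of (animal_id, step, chosen candidate rank, n in-bounds candidates,
    chosen step length) for sampler-fidelity checks.
    """
    from .ssf import EncounterIndex  # analysis-side definition, shared exactly

    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    have_prey = prey_fixes is not None and events is not None and len(events) > 0
    if config.beta_enc != 0.0 and not have_prey:
        raise ValueError("beta_enc != 0 requires prey trajectories with events")

    xmin, ymin, xmax, ymax = landscape.extent
    start = pd.Timestamp(start, tz="UTC")
    dt_min = config.fix_interval_min
    n_steps = int(duration_d * 24 * 60 / dt_min)

    enc_index = None
    if have_prey and config.beta_enc != 0.0:
        enc_index = EncounterIndex(
            prey_fixes,
            events,
            radius_m=config.encounter_radius_m,
            postpartum_window_d=config.postpartum_window_d,
            match_tolerance=pd.Timedelta(minutes=config.match_tolerance_min),
        )

    std_layers = {}
    for name, b in config.beta_true.items():
        v = landscape.layers[name]
        std_layers[name] = ((v - v.mean()) / v.std(), b)
    surf_std = None
    if config.surface is not None and config.surface_weight is not None:
        s = np.asarray(config.surface, dtype=float)
        surf_std = (s - np.nanmean(s)) / np.nanstd(s)

    neutral = (
        not std_layers
        and config.beta_enc == 0.0
        and surf_std is None
        and config.home_range_strength == 0.0
    )

    ss = np.random.SeedSequence(seed)
    rows = []
    diag_rows = []
    M = config.n_candidates
    for i, child in enumerate(ss.spawn(n_animals)):
        rng = np.random.default_rng(child)
        aid = f"{config.species}_{config.sex}_{i:03d}"
        t0 = start + pd.Timedelta(minutes=float(rng.uniform(0, dt_min)))
        times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * dt_min, unit="m")
        t_ns = times.tz_convert("UTC").tz_localize(None).to_numpy(dtype="datetime64[ns]")
        doys = times.dayofyear.to_numpy() + (
            times.hour.to_numpy() + times.minute.to_numpy() / 60.0
        ) / 24.0

        x = np.empty(n_steps + 1)
        y = np.empty(n_steps + 1)
        x[0] = rng.uniform(xmin + 200, xmax - 200)
        y[0] = rng.uniform(ymin + 200, ymax - 200)
        heading = rng.uniform(-np.pi, np.pi)

        for k in range(n_steps):
            lengths = rng.gamma(config.step_shape, config.step_scale_m, M)
            turns = rng.vonmises(config.turn_mu, config.turn_kappa, M)
            heads = heading + turns
            cx = x[k] + lengths * np.cos(heads)
            cy = y[k] + lengths * np.sin(heads)
            ok = landscape.in_bounds(cx, cy)
            if not ok.any():
                # boxed into a corner: reflect candidates back inside
                cx = _reflect(cx, xmin + 1, xmax - 1)
                cy = _reflect(cy, ymin + 1, ymax - 1)
                ok = np.ones(M, dtype=bool)
            if neutral:
                avail = np.flatnonzero(ok)
                choice = int(rng.choice(avail))
            else:
                lin = np.zeros(M)
                if std_layers:
                    r, c = landscape.rowcol(np.where(ok, cx, x[k]), np.where(ok, cy, y[k]))
                    for arr, b in std_layers.values():
                        lin += b * arr[r, c]
                if enc_index is not None:
                    lin += config.beta_enc * enc_index.indicator_at(cx, cy, t_ns[k + 1])
                if surf_std is not None:
                    w = float(config.surface_weight(doys[k + 1]))
                    if w != 0.0:
                        r, c = landscape.rowcol(np.where(ok, cx, x[k]), np.where(ok, cy, y[k]))
                        lin += w * surf_std[r, c]
                if config.home_range_strength > 0.0:
                    d2 = (cx - x[0]) ** 2 + (cy - y[0]) ** 2
                    lin -= config.home_range_strength * d2 / config.home_range_scale_m**2
                lin = np.where(ok, lin, -np.inf)
                p = np.exp(lin - lin.max())
                p /= p.sum()
                choice = int(rng.choice(M, p=p))
            x[k + 1] = cx[choice]
            y[k + 1] = cy[choice]
            heading = heads[choice]
            if return_diagnostics:
                diag_rows.append((aid, k, choice, int(ok.sum()), float(lengths[choice])))

        rows.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "species": config.species,
                    "sex": config.sex,
                    "t": times,
                    "x": x,
                    "y": y,
                }
            )
        )

    fixes = pd.concat(rows, ignore_index=True)
    if return_diagnostics:
        diag = pd.DataFrame(
            diag_rows, columns=["animal_id", "step", "chosen_rank", "n_in_bounds", "step_length"]
        )
        return fixes, diag
    return fixes


# ---------------------------------------------------------------------------
# true-event persistence (synth truth schema)


def write_true_events(events: pd.DataFrame, path: str | Path) -> None:
    """CSV ``animal_id,birth_time_iso8601,birth_x,birth_y``."""
    out = pd.DataFrame(
        {
            "animal_id": events["animal_id"],
            "birth_time_iso8601": pd.to_datetime(events["event_time"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "birth_x": events["x"],
            "birth_y": events["y"],
        }
    )
    out.to_csv(path, index=False)


def read_true_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    return pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "event_time": pd.to_datetime(df["birth_time_iso8601"], utc=True),
            "method": "truth",
            "x": df["birth_x"],
            "y": df["birth_y"],
        }
    )
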