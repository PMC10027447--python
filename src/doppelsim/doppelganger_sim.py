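"""Fixed-timestep Brownian-dynamics simulator that replicates an experiment
ledger one-to-one under four models of viscosity heterogeneity, plus the
physical-constants layer and model calibration.

Models
------
``uniform``   every cell and position shares the population-mean viscosity.
``spatial``   each cell is tiled with square domains of side ``Lambda`` whose
              viscosities are log-normal about the population mean.
``cellular``  each cell gets a single log-normal viscosity about the
              population mean.
``combined``  cellular draw first, then spatial domains about the cell mean.

Each particle steps with independent per-axis Gaussian displacements of
standard deviation ``xi = sqrt(2 kB T dt / gamma)``, with the drag evaluated
from the viscosity at the step's starting position, and is reflected back
into the rectangular cell on boundary crossings.  Simulated ledgers are
exactly equal to their input ledgers (the defining fixed point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .trajectory_model import (
    CellRecord,
    CellStats,
    ExperimentStats,
    Track,
    TrackSet,
)

__all__ = [
    "PhysicalParams",
    "ModelConfig",
    "ViscosityField",
    "water_viscosity",
    "stokes_einstein_diffusivity",
    "drag_coefficient",
    "sample_lognormal_viscosity",
    "build_viscosity_field",
    "viscosity_at",
    "simulate_track",
    "run_doppelganger",
    "calibrate_model",
    "DOMAIN_SIZE_PRESETS",
    "DEFAULT_CELL_WIDTH_NM",
]

MODELS = ("uniform", "spatial", "cellular", "combined")

#: Simulated cells always use this short-axis width (nm); imaging captures
#: only the lower portion of the cell, narrower than the full diameter.
DEFAULT_CELL_WIDTH_NM = 3000.0

#: Best-fit (mean viscosity rel. water, sigma_cell, sigma_spatial) per
#: spatial domain size Lambda (nm), for the combined model.
DOMAIN_SIZE_PRESETS: dict[float, tuple[float, float, float]] = {
    100.0: (50.0, 0.375, 1.1),
    300.0: (39.0, 0.4, 1.0),
    600.0: (38.0, 0.4, 0.9),
    1000.0: (40.5, 0.4, 0.8),
    3000.0: (41.5, 0.0, 0.775),
}


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants of the simulation (pN, nm, ms, K unit system)."""

    k_B: float = 0.0138  # pN nm / K
    T: float = 303.15  # K
    R: float = 20.0  # nm, particle radius
    dt: float = 10.0  # ms

    def __post_init__(self) -> None:
        if min(self.k_B, self.T, self.R, self.dt) <= 0:
            raise ValueError("all physical parameters must be positive")

    @property
    def kT(self) -> float:
        return self.k_B * self.T


@dataclass(frozen=True)
class ModelConfig:
    model: str = "uniform"
    mean_visc_rel_water: float = 40.0
    sigma_cell: float = 0.45  # log-normal shape of the cellular draw
    sigma_spatial: float = 0.85  # log-normal shape of the spatial draw
    domain_size_Lambda: float = 1000.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.sigma_cell < 0 or self.sigma_spatial < 0:
            raise ValueError("shape parameters must be >= 0")
        if self.domain_size_Lambda <= 0:
            raise ValueError("domain size must be > 0")
        if self.mean_visc_rel_water <= 0:
            raise ValueError("mean viscosity multiplier must be > 0")


@dataclass(frozen=True)
class ViscosityField:
    """Per-cell viscosity landscape: a single value or a grid of domains.

    The grid covers ``[0, L] x [0, W]`` with ``Lambda``-sided squares; when a
    cell dimension is not a whole multiple of ``Lambda`` the remainder forms
    its own narrower column (high-x) or row (high-y).  ``grid`` is indexed
    ``[iy, ix]``.
    """

    length_L: float
    width_W: float
    cell_mean_viscosity: float  # pN ms / nm^2
    Lambda: float | None = None
    grid: np.ndarray | None = None  # (n_y, n_x) domain viscosities

    @property
    def is_grid(self) -> bool:
        return self.grid is not None


# ---------------------------------------------------------------------------
# Physical-constants layer


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of water (pN ms/nm^2) from the empirical
    temperature formula ``2.414e-8 * 10**(247.8/(T-140))``."""
    if T <= 150.0:
        raise ValueError(f"temperature {T} K outside the formula's domain")
    return 2.414e-8 * 10.0 ** (247.8 / (T - 140.0))


def drag_coefficient(eta: float, R: float) -> float:
    """Stokes drag gamma = 6 pi eta R (pN ms/nm)."""
    return 6.0 * math.pi * eta * R


def stokes_einstein_diffusivity(p: PhysicalParams, eta: float) -> float:
    """D = kB T / (6 pi eta R), in nm^2/ms."""
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    return p.kT / drag_coefficient(eta, p.R)


def step_sd(p: PhysicalParams, eta: float) -> float:
    """Per-axis Gaussian step SD xi = sqrt(2 kB T dt / gamma), in nm."""
    return math.sqrt(2.0 * p.kT * p.dt / drag_coefficient(eta, p.R))


# ---------------------------------------------------------------------------
# Viscosity fields


def sample_lognormal_viscosity(
    mu: float,
    shape: float,
    n: int,
    rng: np.random.Generator,
    floor: float,
) -> np.ndarray:
    """Draw ``eta_i = mu * exp(shape * z_i)`` with standard-normal ``z``,
    clipping at ``floor`` (viscosities below water are not allowed)."""
    if mu < floor:
        raise ValueError("mu below the viscosity floor")
    if shape < 0:
        raise ValueError("shape must be >= 0")
    vals = mu * np.exp(shape * rng.standard_normal(n))
    return np.maximum(vals, floor)


def _grid_edges(extent: float, Lambda: float) -> np.ndarray:
    """Domain edges along one axis: full Lambda strides plus a remainder."""
    n_full = int(extent // Lambda)
    edges = [i * Lambda for i in range(n_full + 1)]
    if edges[-1] < extent - 1e-9:
        edges.append(extent)
    elif not edges or len(edges) == 1:  # Lambda > extent: single domain
        edges = [0.0, extent]
    return np.asarray(edges)


def build_viscosity_field(
    cell: CellRecord,
    cfg: ModelConfig,
    population_mean_visc: float,
    rng: np.random.Generator,
    floor: float,
) -> ViscosityField:
    """Realize one cell's viscosity landscape under the configured model."""
    L, W = cell.length_L, cell.width_W
    if cfg.model == "uniform":
        return ViscosityField(L, W, population_mean_visc)
    if cfg.model == "cellular":
        eta_c = sample_lognormal_viscosity(
            population_mean_visc, cfg.sigma_cell, 1, rng, floor)[0]
        return ViscosityField(L, W, eta_c)

    # spatial or combined: a grid about the (population or cellular) mean
    if cfg.model == "combined":
        center = sample_lognormal_viscosity(
            population_mean_visc, cfg.sigma_cell, 1, rng, floor)[0]
    else:
        center = population_mean_visc
    x_edges = _grid_edges(L, cfg.domain_size_Lambda)
    y_edges = _grid_edges(W, cfg.domain_size_Lambda)
    n_x, n_y = len(x_edges) - 1, len(y_edges) - 1
    grid = sample_lognormal_viscosity(
        center, cfg.sigma_spatial, n_x * n_y, rng, floor
    ).reshape(n_y, n_x)
    return ViscosityField(L, W, center, Lambda=cfg.domain_size_Lambda, grid=grid)


def viscosity_at(f: ViscosityField, x: float, y: float) -> float:
    """Viscosity at a position; half-open domains, last index clamped so the
    remainder column/row absorbs coordinates past the last full stride."""
    if not (0.0 <= x <= f.length_L and 0.0 <= y <= f.width_W):
        raise ValueError(f"position ({x}, {y}) outside cell box")
    if not f.is_grid:
        return f.cell_mean_viscosity
    ix = min(int(x // f.Lambda), f.grid.shape[1] - 1)
    iy = min(int(y // f.Lambda), f.grid.shape[0] - 1)
    return float(f.grid[iy, ix])


# ---------------------------------------------------------------------------
# Brownian dynamics


def _reflect(v: np.ndarray, extent: float) -> np.ndarray:
    """Fold coordinates into [0, extent] by repeated boundary reflection."""
    period = 2.0 * extent
    v = np.mod(v, period)
    over = v > extent
    v = np.where(over, period - v, v)
    return v


def simulate_track(
    cell: CellRecord,
    f: ViscosityField,
    n_steps: int,
    p: PhysicalParams,
    rng: np.random.Generator,
    *,
    track_id: str = "sim",
) -> Track:
    """Simulate one particle for ``n_steps`` steps (``n_steps + 1`` points).

    The step SD is evaluated from the viscosity at the step's starting
    position; proposals outside the box are folded back by reflection.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    L, W = f.length_L, f.width_W
    start = rng.uniform([0.0, 0.0], [L, W])
    z = rng.standard_normal((n_steps, 2))

    if not f.is_grid:
        # homogeneous: one vectorized cumulative walk
        xi = step_sd(p, f.cell_mean_viscosity)
        raw = start + np.cumsum(xi * z, axis=0)
        pos = np.empty((n_steps + 1, 2))
        pos[0] = start
        pos[1:, 0] = _reflect(raw[:, 0], L)
        pos[1:, 1] = _reflect(raw[:, 1], W)
    else:
        # heterogeneous: per-step viscosity lookup
        pref = math.sqrt(2.0 * p.kT * p.dt / (6.0 * math.pi * p.R))
        inv_lam = 1.0 / f.Lambda
        grid = f.grid
        n_y, n_x = grid.shape
        pos = np.empty((n_steps + 1, 2))
        pos[0] = start
        x, y = float(start[0]), float(start[1])
        for i in range(n_steps):
            ix = min(int(x * inv_lam), n_x - 1)
            iy = min(int(y * inv_lam), n_y - 1)
            xi = pref / math.sqrt(grid[iy, ix])
            x += xi * z[i, 0]
            y += xi * z[i, 1]
            if x < 0.0 or x > L:
                x = float(_reflect(np.array(x), L))
            if y < 0.0 or y > W:
                y = float(_reflect(np.array(y), W))
            pos[i + 1, 0] = x
            pos[i + 1, 1] = y

    return Track(
        track_id=track_id,
        cell_id=cell.cell_id,
        session_id=cell.session_id,
        day_id=cell.day_id,
        frame_interval=p.dt,
        positions=pos,
    )


def run_doppelganger(
    stats: ExperimentStats,
    cfg: ModelConfig,
    p: PhysicalParams | None = None,
) -> TrackSet:
    """Simulate a full Doppelgänger of the ledger.

    One simulated cell per ledger cell (ledger length, 3 um width) and one
    simulated track per ledger duration, with cell/session/day labels copied;
    track durations match the ledger exactly, so
    ``extract_experiment_stats(run_doppelganger(S)) == S``.  Per-cell and
    per-track RNG substreams make the output deterministic given
    ``cfg.seed`` and independent of execution order.
    """
    if stats.n_cells == 0:
        raise ValueError("empty ledger")
    if p is None:
        p = PhysicalParams(dt=stats.frame_interval)
    elif p.dt != stats.frame_interval:
        raise ValueError("PhysicalParams.dt must equal the ledger frame interval")

    floor = water_viscosity(p.T)
    pop_mean = cfg.mean_visc_rel_water * floor

    root = np.random.SeedSequence(cfg.seed)
    cell_seeds = root.spawn(stats.n_cells)

    tracks: list[Track] = []
    cells: list[CellRecord] = []
    for ci, entry in enumerate(stats.cells):
        cell = CellRecord(
            cell_id=entry.cell_id,
            session_id=entry.session_id,
            day_id=entry.day_id,
            length_L=entry.length_L,
            width_W=DEFAULT_CELL_WIDTH_NM,
            empty_after_filter=not entry.durations,
        )
        cells.append(cell)
        sub = cell_seeds[ci].spawn(len(entry.durations) + 1)
        field_rng = np.random.default_rng(sub[0])
        f = build_viscosity_field(cell, cfg, pop_mean, field_rng, floor)
        for ti, dur in enumerate(entry.durations):
            tr = simulate_track(
                cell, f, dur - 1, p, np.random.default_rng(sub[ti + 1]),
                track_id=f"{entry.cell_id}:t{ti}",
            )
            tracks.append(tr)
    prov = {
        "simulation": "doppelganger",
        "model": cfg.model,
        "seed": cfg.seed,
        "mean_visc_rel_water": cfg.mean_visc_rel_water,
        "sigma_cell": cfg.sigma_cell,
        "sigma_spatial": cfg.sigma_spatial,
        "domain_size_Lambda": cfg.domain_size_Lambda,
    }
    return TrackSet(tracks=tracks, cells=cells, provenance=prov)


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationResult:
    config: ModelConfig
    loss: float
    converged: bool
    n_evaluations: int
    replicate_spread: dict = field(default_factory=dict)
    history: list = field(default_factory=list)


def _sim_targets(stats, cfg, p, n_replicates, tau0, n_lags):
    """Measure (median log10 d_app, track var, cell var) from replicate runs."""
    from .heterogeneity_stats import track_and_cell_log10_dapp

    med, tvar, cvar = [], [], []
    for r in range(n_replicates):
        ts = run_doppelganger(stats, replace(cfg, seed=cfg.seed + 7919 * r), p)
        tlog, clog = track_and_cell_log10_dapp(ts, n_lags=n_lags, tau0=tau0)
        med.append(np.mean(tlog))
        tvar.append(np.var(tlog, ddof=1))
        cvar.append(np.var(clog, ddof=1))
    return (
        np.array([np.mean(med), np.mean(tvar), np.mean(cvar)]),
        np.array([np.std(med, ddof=1) if n_replicates > 1 else 0.0,
                  np.std(tvar, ddof=1) if n_replicates > 1 else 0.0,
                  np.std(cvar, ddof=1) if n_replicates > 1 else 0.0]),
    )


def measure_targets(ts: TrackSet, n_lags: int = 7, tau0: float = 100.0) -> dict:
    """Calibration targets of a track set: median log10 d_app (as the mean of
    logs), track-wise variance, and cell-wise variance of log10 d_app."""
    from .heterogeneity_stats import track_and_cell_log10_dapp

    tlog, clog = track_and_cell_log10_dapp(ts, n_lags=n_lags, tau0=tau0)
    return {
        "median_log10_dapp": float(np.mean(tlog)),
        "track_var_log10_dapp": float(np.var(tlog, ddof=1)),
        "cell_var_log10_dapp": float(np.var(clog, ddof=1)),
    }


def calibrate_model(
    stats: ExperimentStats,
    domain_size: float,
    targets: dict,
    *,
    p: PhysicalParams | None = None,
    model: str = "combined",
    n_replicates: int = 2,
    n_iter: int = 10,
    damping: float = 0.8,
    seed: int = 0,
    n_lags: int = 7,
    tau0: float = 100.0,
) -> CalibrationResult:
    """Fit (mean viscosity, sigma_cell, sigma_spatial) so replicate
    Doppelgänger simulations reproduce the target median and variances of
    log10 apparent diffusivity.

    The declared loss is the summed squared mismatch of the three targets
    (all in log10 / log10^2 units).  The parameters map nearly one-to-one
    onto the targets — viscosity sets the median, sigma_cell the cell-wise
    variance, sigma_spatial the track-minus-cell variance — so the search is
    a damped fixed-point iteration on those three channels, warm-started
    from a noise-corrected analytic inversion (the measurement-noise floor
    is estimated from a uniform-model run at the target median).  Common
    random numbers across iterations keep the loss surface coherent;
    everything is deterministic given ``seed``.
    """
    if model not in MODELS or model == "uniform":
        raise ValueError("model must be spatial, cellular, or combined")
    if p is None:
        p = PhysicalParams(dt=stats.frame_interval)
    tgt = np.array([
        targets["median_log10_dapp"],
        targets["track_var_log10_dapp"],
        targets["cell_var_log10_dapp"],
    ])
    if not np.all(np.isfinite(tgt)):
        raise ValueError("targets must be finite")

    floor = water_viscosity(p.T)
    ln10 = math.log(10.0)

    # --- noise floors from a uniform run at the target median diffusivity
    d_med = 10.0 ** tgt[0]
    eta0_rel = p.kT / (drag_coefficient(floor, p.R) * d_med)  # rel. water
    ucfg = ModelConfig(model="uniform", mean_visc_rel_water=eta0_rel,
                       domain_size_Lambda=domain_size, seed=seed)
    (m0, noise_track, noise_cell), _ = _sim_targets(stats, ucfg, p, 1, tau0, n_lags)
    mu_bias = m0 - tgt[0]  # fit bias of the median under pure diffusion
    noise_diff = max(noise_track - noise_cell, 1e-9)

    # --- analytic warm start: log10-variance adds shape^2/ln10^2 per level
    sig_cell_var = max(tgt[2] - noise_cell, 1e-6)
    sig_spatial_var = max(tgt[1] - tgt[2] - noise_diff, 1e-6)
    s_cell = math.sqrt(sig_cell_var) * ln10
    s_spatial = math.sqrt(sig_spatial_var) * ln10
    if model == "spatial":
        s_cell = 0.0
        s_spatial = math.sqrt(max(tgt[1] - noise_track, 1e-6)) * ln10
    elif model == "cellular":
        s_spatial = 0.0
        s_cell = math.sqrt(max(tgt[1] - noise_track, 1e-6)) * ln10
    eta_rel = eta0_rel * 10.0 ** mu_bias

    n_evals = 0
    history: list = []

    def evaluate(eta, sc, ss):
        nonlocal n_evals
        cfg = ModelConfig(model=model, mean_visc_rel_water=eta,
                          sigma_cell=sc, sigma_spatial=ss,
                          domain_size_Lambda=domain_size, seed=seed + 1)
        got, _ = _sim_targets(stats, cfg, p, n_replicates, tau0, n_lags)
        resid = got - tgt
        val = float(resid @ resid)
        n_evals += 1
        history.append((cfg, val))
        return got, val

    def secant_factor(signal_target: float, signal_meas: float) -> float:
        """Multiplicative shape update; shapes enter variances quadratically."""
        if signal_meas <= 0:
            return 1.5
        if signal_target <= 0:
            return 0.5
        return (signal_target / signal_meas) ** (damping / 2.0)

    for _ in range(max(n_iter, 1)):
        (m, tv, cv), loss = evaluate(eta_rel, s_cell, s_spatial)
        if loss < 1e-8:
            break
        # median channel: d(median_log10)/d(ln eta) = -1/ln10
        eta_rel *= math.exp(damping * (m - tgt[0]) * ln10)
        if model in ("cellular", "combined"):
            s_cell *= secant_factor(tgt[2] - noise_cell, cv - noise_cell)
            s_cell = min(max(s_cell, 1e-4), 5.0)
        if model in ("spatial", "combined"):
            ref_floor = noise_diff if model == "combined" else noise_track
            meas = (tv - cv) if model == "combined" else tv
            want = (tgt[1] - tgt[2]) if model == "combined" else tgt[1]
            s_spatial *= secant_factor(want - ref_floor, meas - ref_floor)
            s_spatial = min(max(s_spatial, 1e-4), 5.0)

    best_cfg, best_loss = min(history, key=lambda cl: cl[1])
    _, spread = _sim_targets(stats, best_cfg, p, max(n_replicates, 2), tau0, n_lags)
    noise2 = float(spread @ spread)
    return CalibrationResult(
        config=best_cfg,
        loss=best_loss,
        converged=bool(best_loss < max(1e-4, 9.0 * noise2)),
        n_evaluations=n_evals,
        replicate_spread={
            "median_log10_dapp": float(spread[0]),
            "track_var_log10_dapp": float(spread[1]),
            "cell_var_log10_dapp": float(spread[2]),
        },
        history=history,
    )
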