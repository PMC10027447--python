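"""Time-averaged MSD with nonoverlapping windows, power-law fitting, VAC,
and bootstrap confidence intervals.

The windowed time average at lag ``k`` frames tiles a track from its first
point in strides of ``k``, discarding any remainder; per-axis squared
displacements are averaged over windows and summed over x and y.  A track of
7 points at lag 3 therefore contributes two windows per axis:
``((x4-x1)^2 + (x7-x4)^2)/2``.

Fits are ordinary least squares of ``ln(MSD)`` against ``ln(tau/tau0)`` over
the first ``n_lags`` available lags; ``alpha`` is the slope and the amplitude
``A = exp(intercept)`` converts to an apparent diffusivity
``D_app = A / (2 * n_dims * tau0)`` with ``n_dims = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_model import Track, TrackSet

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "VACCurve",
    "FitError",
    "time_averaged_msd",
    "ensemble_average_msd",
    "fit_power_law",
    "fit_hierarchy",
    "velocity_autocorrelation",
    "ensemble_vac",
    "bootstrap_fit_ci",
]

N_DIMS = 2
DEFAULT_N_LAGS = 7
DEFAULT_TAU0_MS = 100.0


class FitError(ValueError):
    """Raised when an MSD curve cannot be fit (e.g. non-positive values)."""


@dataclass(frozen=True)
class MSDCurve:
    """MSD per lag.  ``n_contrib`` counts windows (single track) or tracks
    (ensemble curves); ``se`` is NaN where undefined."""

    lags: np.ndarray  # ms, strictly increasing
    msd: np.ndarray  # nm^2
    se: np.ndarray  # nm^2
    n_contrib: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        if lags.size and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", np.asarray(self.msd, dtype=float))
        object.__setattr__(self, "se", np.asarray(self.se, dtype=float))
        object.__setattr__(self, "n_contrib", np.asarray(self.n_contrib, dtype=int))


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    amplitude_A: float  # nm^2 at tau0
    d_app: float  # nm^2/ms at tau0
    tau0: float = DEFAULT_TAU0_MS
    n_lags_fit: int = DEFAULT_N_LAGS
    n_dims: int = N_DIMS
    ci95: dict | None = None  # {"alpha": (lo, hi), "d_app": (lo, hi)}


@dataclass(frozen=True)
class VACCurve:
    lags: np.ndarray  # ms
    vac: np.ndarray  # nm^2/ms^2
    se: np.ndarray


def time_averaged_msd(tr: Track, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one track using nonoverlapping windows.

    Lags with zero complete windows are absent from the curve.
    """
    n = tr.n_points
    if n < 2:
        raise ValueError("track needs >= 2 points")
    if max_lag is None:
        max_lag = n - 1
    pos = tr.positions
    lags, msds, ses, counts = [], [], [], []
    for k in range(1, min(max_lag, n - 1) + 1):
        idx = np.arange(0, n, k)
        if idx.size < 2:
            break
        d = pos[idx[1:]] - pos[idx[:-1]]  # (n_windows, 2)
        sq = np.sum(d * d, axis=1)
        lags.append(k * tr.frame_interval)
        msds.append(sq.mean())
        counts.append(sq.size)
        ses.append(sq.std(ddof=1) / np.sqrt(sq.size) if sq.size > 1 else np.nan)
    return MSDCurve(np.array(lags), np.array(msds), np.array(ses), np.array(counts))


def ensemble_average_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Unweighted per-lag mean across curves; absent lags are ignored.

    ``se`` is the SD across contributing curves over sqrt(count).
    """
    if not curves:
        raise ValueError("no curves to average")
    pool: dict[float, list[float]] = {}
    for c in curves:
        for lag, m in zip(c.lags, c.msd):
            pool.setdefault(float(lag), []).append(float(m))
    lags = np.array(sorted(pool))
    msd = np.empty_like(lags)
    se = np.empty_like(lags)
    n = np.empty(lags.size, dtype=int)
    for i, lag in enumerate(lags):
        vals = np.asarray(pool[lag])
        msd[i] = vals.mean()
        n[i] = vals.size
        se[i] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
    return MSDCurve(lags, msd, se, n)


def fit_power_law(
    curve: MSDCurve,
    n_lags: int = DEFAULT_N_LAGS,
    tau0: float = DEFAULT_TAU0_MS,
) -> PowerLawFit:
    """OLS fit of ln(MSD) vs ln(tau/tau0) over the first ``n_lags`` lags."""
    lags = curve.lags[:n_lags]
    msd = curve.msd[:n_lags]
    if lags.size < 2:
        raise FitError("need >= 2 lags to fit")
    if np.any(msd <= 0):
        raise FitError("non-positive MSD among fitted lags")
    x = np.log(lags / tau0)
    y = np.log(msd)
    slope, intercept = np.polyfit(x, y, 1)
    A = float(np.exp(intercept))
    return PowerLawFit(
        alpha=float(slope),
        amplitude_A=A,
        d_app=A / (2 * N_DIMS * tau0),
        tau0=tau0,
        n_lags_fit=int(lags.size),
    )


def fit_hierarchy(
    ts: TrackSet,
    level: str = "track",
    n_lags: int = DEFAULT_N_LAGS,
    tau0: float = DEFAULT_TAU0_MS,
) -> dict[str, PowerLawFit | None]:
    """Fit per track, per cell, or for the whole condition.

    Track-wise fits use each track's own time-averaged curve; cell- and
    condition-wise fits first ensemble-average the time-averaged curves over
    the unit's tracks.  Units that cannot be fit map to ``None``.
    """
    if level not in ("track", "cell", "condition"):
        raise ValueError(f"unknown level {level!r}")
    max_lag = n_lags

    def _safe_fit(curves: list[MSDCurve]):
        try:
            return fit_power_law(ensemble_average_msd(curves), n_lags, tau0)
        except (FitError, ValueError):
            return None

    if level == "track":
        out: dict[str, PowerLawFit | None] = {}
        for tr in ts.tracks:
            out[tr.track_id] = _safe_fit([time_averaged_msd(tr, max_lag)])
        return out
    if level == "cell":
        by_cell = ts.tracks_by_cell()
        return {
            cid: (_safe_fit([time_averaged_msd(t, max_lag) for t in trs]) if trs else None)
            for cid, trs in by_cell.items()
        }
    curves = [time_averaged_msd(tr, max_lag) for tr in ts.tracks]
    return {"condition": _safe_fit(curves)}


def track_fit_table(ts: TrackSet, n_lags: int = DEFAULT_N_LAGS,
                    tau0: float = DEFAULT_TAU0_MS):
    """Track-wise fits as parallel arrays (ids, alphas, d_apps, cell labels),
    excluding tracks whose fit failed."""
    fits = fit_hierarchy(ts, "track", n_lags, tau0)
    cell_of = {tr.track_id: tr.cell_id for tr in ts.tracks}
    sess_of = {tr.track_id: tr.session_id for tr in ts.tracks}
    day_of = {tr.track_id: tr.day_id for tr in ts.tracks}
    ids = [tid for tid, f in fits.items() if f is not None]
    return {
        "track_id": ids,
        "cell_id": [cell_of[t] for t in ids],
        "session_id": [sess_of[t] for t in ids],
        "day_id": [day_of[t] for t in ids],
        "alpha": np.array([fits[t].alpha for t in ids]),
        "d_app": np.array([fits[t].d_app for t in ids]),
    }


# ---------------------------------------------------------------------------
# Velocity autocorrelation


def velocity_autocorrelation(tr: Track, max_lag: int | None = None) -> VACCurve:
    """VAC(tau) over nonoverlapping velocity pairs.

    ``v(t)`` is the single-frame displacement divided by the frame interval;
    VAC(0) is the mean squared speed.  For lag ``k`` the pairs
    ``(v[j], v[j+k])`` start at ``j = 0, k+1, 2(k+1), ...`` so no velocity
    sample is reused within a lag.
    """
    if tr.n_points < 3:
        raise ValueError("track needs >= 3 points")
    dt = tr.frame_interval
    v = np.diff(tr.positions, axis=0) / dt  # (n-1, 2)
    nv = v.shape[0]
    if max_lag is None:
        max_lag = nv - 1
    lags, vacs, ses = [0.0], [], []
    sq = np.sum(v * v, axis=1)
    vacs.append(sq.mean())
    ses.append(sq.std(ddof=1) / np.sqrt(sq.size) if sq.size > 1 else np.nan)
    for k in range(1, min(max_lag, nv - 1) + 1):
        starts = np.arange(0, nv - k, k + 1)
        dots = np.sum(v[starts] * v[starts + k], axis=1)
        lags.append(k * dt)
        vacs.append(dots.mean())
        ses.append(dots.std(ddof=1) / np.sqrt(dots.size) if dots.size > 1 else np.nan)
    return VACCurve(np.array(lags), np.array(vacs), np.array(ses))


def ensemble_vac(ts: TrackSet, max_lag: int) -> VACCurve:
    """Per-lag unweighted mean of track VACs across the set."""
    pool: dict[float, list[float]] = {}
    for tr in ts.tracks:
        if tr.n_points < 3:
            continue
        c = velocity_autocorrelation(tr, max_lag)
        for lag, val in zip(c.lags, c.vac):
            pool.setdefault(float(lag), []).append(float(val))
    if not pool:
        raise ValueError("no tracks with >= 3 points")
    lags = np.array(sorted(pool))
    vac = np.array([np.mean(pool[l]) for l in lags])
    se = np.array([
        np.std(pool[l], ddof=1) / np.sqrt(len(pool[l])) if len(pool[l]) > 1 else np.nan
        for l in lags
    ])
    return VACCurve(lags, vac, se)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_fit_ci(
    curves: list[MSDCurve],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    n_lags: int = DEFAULT_N_LAGS,
    tau0: float = DEFAULT_TAU0_MS,
) -> dict[str, tuple[float, float]]:
    """Basic-percentile 95% CI for (alpha, d_app) of the ensemble fit.

    Each draw resamples whole tracks (curves) with replacement, sample size
    equal to the number of tracks, re-averages and refits.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(curves)
    alphas, dapps = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            f = fit_power_law(ensemble_average_msd([curves[i] for i in idx]), n_lags, tau0)
        except FitError:
            continue
        alphas.append(f.alpha)
        dapps.append(f.d_app)
    return {
        "alpha": tuple(np.percentile(alphas, [2.5, 97.5])),
        "d_app": tuple(np.percentile(dapps, [2.5, 97.5])),
    }
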