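"""Ensemble- vs time-ensemble-averaged MSD comparison, percent-difference
decay fitting, and domain-size scans.

The EA MSD is the squared displacement from each track's first frame,
averaged over all tracks alive at the lag; the TEA MSD is the ensemble of
time-averaged curves from :mod:`doppelsim.msd_analysis` (single MSD
implementation in the codebase).  Their percent difference
``(EA - TEA) * 100 / EA`` decays with lag when slow regions accumulate
occupancy, and is fit by ``A * exp(-B t) + C``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .doppelganger_sim import (
    DOMAIN_SIZE_PRESETS,
    ModelConfig,
    PhysicalParams,
    run_doppelganger,
)
from .msd_analysis import MSDCurve, ensemble_average_msd, time_averaged_msd
from .trajectory_model import ExperimentStats, TrackSet

__all__ = [
    "ErgodicityCurves",
    "ExpDecayFit",
    "ensemble_msd",
    "ergodicity_percent_difference",
    "ergodicity_curves",
    "fit_exp_decay",
    "domain_size_scan",
]


@dataclass(frozen=True)
class ErgodicityCurves:
    lags: np.ndarray  # ms
    ea_msd: np.ndarray  # nm^2
    ea_ci95: np.ndarray  # (n_lags, 2)
    tea_msd: np.ndarray  # nm^2
    percent_diff: np.ndarray  # %
    percent_diff_se: np.ndarray  # bootstrap SE of the % difference
    n_contrib: np.ndarray


@dataclass(frozen=True)
class ExpDecayFit:
    A: float  # decaying amplitude (%)
    B: float  # rate (1/ms)
    C: float  # plateau (%)
    residual_norm: float
    converged: bool = True


def _from_origin_sq(ts: TrackSet, max_lag: int) -> np.ndarray:
    """Matrix (n_tracks, max_lag) of |x(k)-x(0)|^2, NaN past track end."""
    out = np.full((ts.n_tracks, max_lag), np.nan)
    for i, tr in enumerate(ts.tracks):
        kmax = min(max_lag, tr.n_points - 1)
        if kmax < 1:
            continue
        d = tr.positions[1:kmax + 1] - tr.positions[0]
        out[i, :kmax] = np.sum(d * d, axis=1)
    return out


def ensemble_msd(
    ts: TrackSet,
    max_lag: int,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
) -> MSDCurve:
    """From-origin ensemble MSD with a basic-percentile bootstrap 95% CI
    stored in the curve's ``se`` field as half the CI width / 1.96."""
    if ts.n_tracks == 0:
        raise ValueError("empty TrackSet")
    sq = _from_origin_sq(ts, max_lag)
    with np.errstate(invalid="ignore"):
        msd = np.nanmean(sq, axis=0)
    n = np.sum(~np.isnan(sq), axis=0)
    keep = n >= 1
    dt = ts.tracks[0].frame_interval
    lags = (np.arange(1, max_lag + 1) * dt)[keep]

    rng = np.random.default_rng(seed)
    n_tracks = sq.shape[0]
    boots = np.empty((n_boot, int(keep.sum())))
    for b in range(n_boot):
        idx = rng.integers(0, n_tracks, n_tracks)
        with np.errstate(invalid="ignore"):
            boots[b] = np.nanmean(sq[idx][:, keep], axis=0)
    se = np.nanstd(boots, axis=0, ddof=1)
    return MSDCurve(lags, msd[keep], se, n[keep])


def tea_msd(ts: TrackSet, max_lag: int) -> MSDCurve:
    """Time-then-ensemble-averaged MSD (the analysis-wide TEA definition)."""
    curves = [time_averaged_msd(tr, max_lag) for tr in ts.tracks if tr.n_points >= 2]
    return ensemble_average_msd(curves)


def ergodicity_percent_difference(ea: MSDCurve, tea: MSDCurve) -> MSDCurve:
    """(EA - TEA) * 100 / EA on the shared lags; lags with EA = 0 dropped."""
    common = np.intersect1d(ea.lags, tea.lags)
    ia = np.searchsorted(ea.lags, common)
    it = np.searchsorted(tea.lags, common)
    ea_v, tea_v = ea.msd[ia], tea.msd[it]
    ok = ea_v > 0
    pct = (ea_v[ok] - tea_v[ok]) * 100.0 / ea_v[ok]
    n = np.minimum(ea.n_contrib[ia], tea.n_contrib[it])[ok]
    return MSDCurve(common[ok], pct, np.full(ok.sum(), np.nan), n)


def ergodicity_curves(
    ts: TrackSet,
    max_lag: int,
    n_boot: int = 500,
    seed: int = 0,
) -> ErgodicityCurves:
    """EA/TEA curves with a joint track-resampling bootstrap.

    Each bootstrap draw resamples tracks once and recomputes EA, TEA and the
    percent difference from the same resample, so the percent-difference SE
    reflects their covariance.
    """
    if ts.n_tracks == 0:
        raise ValueError("empty TrackSet")
    dt = ts.tracks[0].frame_interval
    sq = _from_origin_sq(ts, max_lag)

    ta_curves = [time_averaged_msd(tr, max_lag) for tr in ts.tracks]
    # dense TA matrix aligned to integer lags
    ta = np.full((ts.n_tracks, max_lag), np.nan)
    for i, c in enumerate(ta_curves):
        ki = np.rint(c.lags / dt).astype(int) - 1
        ta[i, ki] = c.msd

    with np.errstate(invalid="ignore"):
        ea = np.nanmean(sq, axis=0)
        tea = np.nanmean(ta, axis=0)
    n_ea = np.sum(~np.isnan(sq), axis=0)
    keep = (n_ea >= 1) & ~np.isnan(tea) & (ea > 0)

    rng = np.random.default_rng(seed)
    n_tracks = ts.n_tracks
    ea_b = np.empty((n_boot, int(keep.sum())))
    pd_b = np.empty_like(ea_b)
    for b in range(n_boot):
        idx = rng.integers(0, n_tracks, n_tracks)
        with np.errstate(invalid="ignore"):
            ea_i = np.nanmean(sq[idx][:, keep], axis=0)
            tea_i = np.nanmean(ta[idx][:, keep], axis=0)
        ea_b[b] = ea_i
        with np.errstate(invalid="ignore", divide="ignore"):
            pd_b[b] = (ea_i - tea_i) * 100.0 / ea_i
    ci = np.nanpercentile(ea_b, [2.5, 97.5], axis=0).T
    pd_se = np.nanstd(pd_b, axis=0, ddof=1)

    lags = (np.arange(1, max_lag + 1) * dt)[keep]
    pct = (ea[keep] - tea[keep]) * 100.0 / ea[keep]
    return ErgodicityCurves(
        lags=lags, ea_msd=ea[keep], ea_ci95=ci, tea_msd=tea[keep],
        percent_diff=pct, percent_diff_se=pd_se, n_contrib=n_ea[keep],
    )


def fit_exp_decay(
    lags: np.ndarray,
    y: np.ndarray,
    se: np.ndarray | None = None,
) -> ExpDecayFit:
    """Weighted nonlinear least squares of ``y = A exp(-B t) + C``.

    Weights are 1/se when provided.  Initialization: plateau from the tail
    mean, amplitude from the head, rate from the lag where the centered
    signal halves.
    """
    t = np.asarray(lags, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 points")
    n_tail = max(t.size // 4, 1)
    c0 = float(np.mean(y[-n_tail:]))
    a0 = float(np.mean(y[:n_tail]) - c0)
    b0 = 1.0 / float(t[min(t.size - 1, t.size // 3)])
    if a0 != 0.0:
        centered = (y - c0) / a0
        below = np.where(centered < 0.5)[0]
        if below.size and t[below[0]] > 0:
            b0 = np.log(2.0) / float(t[below[0]])

    sigma = None
    if se is not None:
        sigma = np.asarray(se, dtype=float).copy()
        bad = ~np.isfinite(sigma) | (sigma <= 0)
        if bad.all():
            sigma = None
        elif bad.any():
            sigma[bad] = np.nanmax(sigma[~bad])

    def model(tt, A, B, C):
        return A * np.exp(-B * tt) + C

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[a0, b0, c0], sigma=sigma,
            maxfev=20000, xtol=1e-10, ftol=1e-12,
        )
        converged = True
    except RuntimeError:
        popt, converged = np.array([a0, b0, c0]), False
    resid = y - model(t, *popt)
    if sigma is not None:
        resid = resid / sigma
    return ExpDecayFit(A=float(popt[0]), B=float(popt[1]), C=float(popt[2]),
                       residual_norm=float(np.linalg.norm(resid)),
                       converged=converged)


def domain_size_scan(
    stats: ExperimentStats,
    sizes: list[float] | None = None,
    configs: dict[float, ModelConfig] | None = None,
    n_replicates: int = 50,
    max_lag: int = 30,
    n_boot: int = 200,
    seed: int = 0,
    min_tracks_per_lag: int = 10,
    p: PhysicalParams | None = None,
) -> dict[float, dict]:
    """Replicate Doppelgänger scans over spatial domain sizes.

    For each size: ``n_replicates`` full simulations, a percent-difference
    curve and decay fit per replicate, and the replicate-averaged fit
    parameters.  Sizes default to the preset table; configs default to the
    per-size best-fit parameters.  Lags with fewer than
    ``min_tracks_per_lag`` contributing tracks are excluded from fits.
    """
    if sizes is None:
        sizes = sorted(DOMAIN_SIZE_PRESETS)
    out: dict[float, dict] = {}
    for si, size in enumerate(sizes):
        if configs is not None and size in configs:
            cfg = configs[size]
        elif size in DOMAIN_SIZE_PRESETS:
            mean, sc, ss = DOMAIN_SIZE_PRESETS[size]
            cfg = ModelConfig(model="combined", mean_visc_rel_water=mean,
                              sigma_cell=sc, sigma_spatial=ss,
                              domain_size_Lambda=size)
        else:
            raise ValueError(f"no config for domain size {size}")
        curves, fits = [], []
        for r in range(n_replicates):
            rep_seed = seed + 100_003 * si + r
            ts = run_doppelganger(stats, replace(cfg, seed=rep_seed), p)
            ec = ergodicity_curves(ts, max_lag, n_boot=n_boot, seed=rep_seed)
            ok = ec.n_contrib >= min_tracks_per_lag
            curves.append(ec)
            if ok.sum() >= 4:
                fits.append(fit_exp_decay(ec.lags[ok], ec.percent_diff[ok],
                                          ec.percent_diff_se[ok]))
        mean_fit = None
        if fits:
            mean_fit = ExpDecayFit(
                A=float(np.mean([f.A for f in fits])),
                B=float(np.mean([f.B for f in fits])),
                C=float(np.mean([f.C for f in fits])),
                residual_norm=float(np.mean([f.residual_norm for f in fits])),
                converged=all(f.converged for f in fits),
            )
        out[size] = {"config": cfg, "curves": curves, "fits": fits,
                     "mean_fit": mean_fit}
    return out
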