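"""Synthetic experiment ledgers and reference diffusivity distributions.

Generates ledgers whose summary statistics emulate the published dataset
summary (145 cells, ~25 +/- 10 tracks per cell, exponentially decaying track
durations with mean 273 ms and a 10-frame minimum at a 10 ms frame interval,
a two-fold range of cell lengths, 5 sessions over 3 days), plus hierarchical
log-normal reference diffusivities with a configurable intrinsic/extrinsic
variance split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .trajectory_model import CellStats, ExperimentStats

__all__ = [
    "SynthConfig",
    "ReferenceDistributionConfig",
    "generate_experiment_stats",
    "generate_reference_diffusivities",
    "truncated_exponential_mean",
]


@dataclass(frozen=True)
class SynthConfig:
    n_cells: int = 145
    tracks_per_cell_mean: float = 25.0
    tracks_per_cell_sd: float = 10.0
    tracks_per_cell_min: int = 1
    duration_mean_ms: float = 273.0
    duration_min_ms: float = 100.0  # 10 frames at 10 ms
    duration_max_ms: float = 10_000.0  # acquisition window
    frame_interval_ms: float = 10.0
    cell_length_min_nm: float = 7_000.0
    cell_length_max_nm: float = 14_000.0
    n_sessions: int = 5
    n_days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min_ms < 10 * self.frame_interval_ms:
            raise ValueError("duration minimum must be >= 10 frames")
        if not (0 < self.duration_min_ms < self.duration_mean_ms
                < self.duration_max_ms):
            raise ValueError("need min < mean < max duration")


@dataclass(frozen=True)
class ReferenceDistributionConfig:
    """Targets of the hierarchical log-normal reference distribution.

    Diffusivities are in nm^2/ms internally (0.29 um^2/s = 290 nm^2/ms);
    fold ranges follow the ``10**(5 sigma_log)`` convention, so the
    track-level sigma_log is ``log10(fold_range)/5``.
    """

    track_median_um2_s: float = 0.29
    track_fold_range: float = 392.0
    extrinsic_fraction: float = 0.2  # cell-level share of the track variance
    seed: int = 0

    @property
    def mu_log(self) -> float:  # log10 nm^2/ms
        return math.log10(self.track_median_um2_s * 1000.0)

    @property
    def sigma_track(self) -> float:
        return math.log10(self.track_fold_range) / 5.0


def truncated_exponential_mean(scale: float, lo: float, hi: float) -> float:
    """Mean of an exponential(scale) truncated to [lo, hi] (closed form)."""
    span = hi - lo
    r = span / scale
    if r > 700:  # upper tail numerically gone
        return lo + scale
    return lo + scale - span * math.exp(-r) / (1.0 - math.exp(-r))


def _solve_truncexp_scale(target_mean: float, lo: float, hi: float) -> float:
    """Scale whose truncated mean matches ``target_mean``."""
    f = lambda s: truncated_exponential_mean(s, lo, hi) - target_mean
    return optimize.brentq(f, 1e-3, hi)


def generate_experiment_stats(cfg: SynthConfig) -> ExperimentStats:
    """Generate a synthetic ledger, deterministic given ``cfg.seed``.

    Per-cell track counts are rounded truncated normals; durations are
    i.i.d. truncated exponentials (the scale is solved so the truncated mean
    equals the configured mean) converted to whole frames; cells go
    round-robin to sessions and sessions round-robin to days.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval_ms
    scale = _solve_truncexp_scale(cfg.duration_mean_ms, cfg.duration_min_ms,
                                  cfg.duration_max_ms)
    lo_cdf = 1.0 - math.exp(-cfg.duration_min_ms / scale)
    hi_cdf = 1.0 - math.exp(-cfg.duration_max_ms / scale)

    min_frames = int(round(cfg.duration_min_ms / dt))
    max_frames = int(round(cfg.duration_max_ms / dt))

    cells = []
    for i in range(cfg.n_cells):
        n_tracks = max(
            cfg.tracks_per_cell_min,
            int(round(rng.normal(cfg.tracks_per_cell_mean, cfg.tracks_per_cell_sd))),
        )
        u = rng.uniform(lo_cdf, hi_cdf, size=n_tracks)
        dur_ms = -scale * np.log1p(-u)
        frames = np.clip(np.rint(dur_ms / dt).astype(int), min_frames, max_frames)
        session = i % cfg.n_sessions
        day = session % cfg.n_days
        cells.append(
            CellStats(
                cell_id=f"cell{i:03d}",
                session_id=f"s{session}",
                day_id=f"d{day}",
                length_L=float(rng.uniform(cfg.cell_length_min_nm,
                                           cfg.cell_length_max_nm)),
                durations=tuple(int(f) for f in frames),
            )
        )
    return ExperimentStats(cells=tuple(cells), frame_interval=dt)


def generate_reference_diffusivities(
    stats: ExperimentStats,
    cfg: ReferenceDistributionConfig,
) -> dict:
    """Per-track log10 diffusivities with cell/session/day labels.

    ``value = mu_log + cell_effect + track_effect`` with the cell effect
    carrying the extrinsic share of the track-level variance and the track
    effect the remainder.
    """
    if stats.n_cells == 0:
        raise ValueError("empty ledger")
    rng = np.random.default_rng(cfg.seed)
    s2 = cfg.sigma_track ** 2
    sd_cell = math.sqrt(cfg.extrinsic_fraction * s2)
    sd_track = math.sqrt((1.0 - cfg.extrinsic_fraction) * s2)

    values, cell_ids, session_ids, day_ids = [], [], [], []
    for entry in stats.cells:
        cell_eff = rng.normal(0.0, sd_cell) if sd_cell > 0 else 0.0
        for _ in entry.durations:
            values.append(cfg.mu_log + cell_eff + rng.normal(0.0, sd_track))
            cell_ids.append(entry.cell_id)
            session_ids.append(entry.session_id)
            day_ids.append(entry.day_id)
    return {
        "log10_d_app": np.asarray(values),
        "cell_id": cell_ids,
        "session_id": session_ids,
        "day_id": day_ids,
    }
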