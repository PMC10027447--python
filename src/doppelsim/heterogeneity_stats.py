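"""Spread statistics for apparent diffusivities: log-space summaries and
fold ranges, nested ANOVA variance fractions, Levene and rank-sum
comparisons, within-cell pair correlations, and per-cell CV diagnostics.

All spread statistics operate on log10 values; the "median" of a log-space
distribution is the mean of the logs (the median order of magnitude) and the
fold range is ``10**(5 * sigma_log)`` — the ratio of values 2.5 SD either
side of the center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .msd_analysis import track_fit_table
from .trajectory_model import TrackSet

__all__ = [
    "LogSummary",
    "VarianceDecomposition",
    "GroupComparison",
    "log_space_summary",
    "nested_anova_fractions",
    "levene_test",
    "wilcoxon_rank_sum",
    "within_cell_pair_correlation",
    "per_cell_cv",
    "track_and_cell_log10_dapp",
]

ANOVA_LEVELS = ("day", "session", "cell", "track")


@dataclass(frozen=True)
class LogSummary:
    mu_log: float  # mean of log10 values ("median order of magnitude")
    sigma_log: float  # SD of log10 values
    n: int

    @property
    def median_linear(self) -> float:
        return 10.0 ** self.mu_log

    @property
    def fold_range(self) -> float:
        return 10.0 ** (5.0 * self.sigma_log)


@dataclass(frozen=True)
class VarianceDecomposition:
    fraction_by_level: dict[str, float]
    total_variance: float  # log10 units squared (total SS / (n-1))

    def __post_init__(self) -> None:
        total = sum(self.fraction_by_level.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class GroupComparison:
    test: str  # levene | ranksum | spearman
    statistic: float
    p_value: float
    effect: dict | None = None

    def __post_init__(self) -> None:
        # NaN p is allowed (degenerate inputs, e.g. constant correlations)
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def log_space_summary(values: np.ndarray) -> LogSummary:
    """Log10 center/spread of positive diffusivities (population SD)."""
    v = np.asarray(values, dtype=float)
    bad = np.where(~(v > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive value at index {bad[0]}: {v[bad[0]]}")
    logs = np.log10(v)
    return LogSummary(mu_log=float(logs.mean()), sigma_log=float(logs.std()),
                      n=v.size)


def nested_anova_fractions(
    values: np.ndarray,
    labels: list[tuple],
) -> VarianceDecomposition:
    """Sequential nested sums-of-squares decomposition.

    ``labels[i] = (day, session, cell)`` for ``values[i]``; tracks are the
    residual level.  The hierarchy must nest cleanly (each cell within one
    session, each session within one day).  For nested groupings the four
    sums of squares are orthogonal and add up to the total exactly.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 values")
    if len(labels) != y.size:
        raise ValueError("labels/values length mismatch")
    days = np.array([l[0] for l in labels], dtype=object)
    sessions = np.array([f"{l[0]}/{l[1]}" for l in labels], dtype=object)
    cells = np.array([f"{l[0]}/{l[1]}/{l[2]}" for l in labels], dtype=object)

    # consistency: a raw session label may not appear under two days, nor a
    # raw cell label under two sessions
    for child, parent, what in (
        ([l[1] for l in labels], days, "session"),
        ([l[2] for l in labels], sessions, "cell"),
    ):
        seen: dict = {}
        for c, p in zip(child, parent):
            if seen.setdefault(c, p) != p:
                raise ValueError(f"{what} {c!r} appears under multiple parents")

    grand = y.mean()

    def group_means(keys):
        out = np.empty_like(y)
        for k in np.unique(keys):
            m = keys == k
            out[m] = y[m].mean()
        return out

    m_day = group_means(days)
    m_sess = group_means(sessions)
    m_cell = group_means(cells)

    ss_day = float(np.sum((m_day - grand) ** 2))
    ss_sess = float(np.sum((m_sess - m_day) ** 2))
    ss_cell = float(np.sum((m_cell - m_sess) ** 2))
    ss_track = float(np.sum((y - m_cell) ** 2))
    ss_total = ss_day + ss_sess + ss_cell + ss_track
    if ss_total == 0.0:
        fracs = {"day": 0.0, "session": 0.0, "cell": 0.0, "track": 1.0}
    else:
        fracs = {
            "day": ss_day / ss_total,
            "session": ss_sess / ss_total,
            "cell": ss_cell / ss_total,
            "track": ss_track / ss_total,
        }
    return VarianceDecomposition(
        fraction_by_level=fracs,
        total_variance=ss_total / (y.size - 1),
    )


def levene_test(group_a: np.ndarray, group_b: np.ndarray) -> GroupComparison:
    """Classic Levene test (absolute deviations from each group's mean)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    dev_a = np.abs(a - a.mean())
    dev_b = np.abs(b - b.mean())
    if np.all(dev_a == 0) and np.all(dev_b == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = sstats.levene(a, b, center="mean")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    return GroupComparison(
        test="levene", statistic=float(stat), p_value=float(p),
        effect={"var_a": float(var_a), "var_b": float(var_b),
                "pct_change_var": float(100.0 * (var_b - var_a) / var_a)
                if var_a > 0 else np.nan},
    )


def wilcoxon_rank_sum(group_a: np.ndarray, group_b: np.ndarray) -> GroupComparison:
    """Two-sided rank-sum test: exact enumeration for combined n <= 20 with
    no ties, otherwise normal approximation with tie and continuity
    corrections."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 value")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = np.median(a), np.median(b)
    return GroupComparison(
        test="ranksum", statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        effect={"median_a": float(med_a), "median_b": float(med_b),
                "method": method},
    )


def within_cell_pair_correlation(
    d_app: np.ndarray,
    cell_ids: list,
    seed: int | np.random.Generator = 0,
) -> GroupComparison:
    """Spearman correlation of one random unordered within-cell pair per
    eligible cell (>= 2 tracks); order within each pair is randomized."""
    rng = np.random.default_rng(seed)
    d_app = np.asarray(d_app, dtype=float)
    by_cell: dict = {}
    for v, c in zip(d_app, cell_ids):
        by_cell.setdefault(c, []).append(v)
    firsts, seconds = [], []
    for c in sorted(by_cell, key=str):
        vals = by_cell[c]
        if len(vals) < 2:
            continue
        i, j = rng.choice(len(vals), size=2, replace=False)
        firsts.append(vals[i])
        seconds.append(vals[j])
    if len(firsts) < 2:
        raise ValueError("need >= 2 cells with >= 2 tracks each")
    r, p = sstats.spearmanr(firsts, seconds)
    return GroupComparison(
        test="spearman", statistic=float(r), p_value=float(p),
        effect={"n_pairs": len(firsts)},
    )


def per_cell_cv(d_app: np.ndarray, cell_ids: list) -> dict:
    """Linear-scale CV of d_app per cell (>= 2 tracks), plus Spearman
    correlations of CV against the cell mean and against track count."""
    d_app = np.asarray(d_app, dtype=float)
    by_cell: dict = {}
    for v, c in zip(d_app, cell_ids):
        by_cell.setdefault(c, []).append(v)
    rows = []
    for c in sorted(by_cell, key=str):
        vals = np.asarray(by_cell[c])
        if vals.size < 2:
            continue
        mean = vals.mean()
        cv = vals.std(ddof=1) / mean if mean > 0 else np.nan
        rows.append((c, float(mean), float(cv), int(vals.size)))
    if len(rows) < 2:
        raise ValueError("need >= 2 cells with >= 2 track fits")
    means = np.array([r[1] for r in rows])
    cvs = np.array([r[2] for r in rows])
    counts = np.array([r[3] for r in rows])
    r_mean, p_mean = sstats.spearmanr(cvs, means)
    r_count, p_count = sstats.spearmanr(cvs, counts)
    return {
        "table": rows,  # (cell_id, mean_d_app, cv, n_tracks)
        "cv_vs_mean": GroupComparison("spearman", float(r_mean), float(p_mean)),
        "cv_vs_count": GroupComparison("spearman", float(r_count), float(p_count)),
    }


# ---------------------------------------------------------------------------
# Convenience bridge used by calibration and the CLI


def track_and_cell_log10_dapp(
    ts: TrackSet, n_lags: int = 7, tau0: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """log10 apparent diffusivities at the track and cell levels.

    Track-wise values come from per-track fits; cell-wise values from fits
    of per-cell ensemble-averaged curves (cells whose fit fails are absent).
    """
    from .msd_analysis import fit_hierarchy

    tab = track_fit_table(ts, n_lags=n_lags, tau0=tau0)
    tmask = tab["d_app"] > 0
    tlog = np.log10(tab["d_app"][tmask])
    cell_fits = fit_hierarchy(ts, "cell", n_lags=n_lags, tau0=tau0)
    cvals = np.array([f.d_app for f in cell_fits.values()
                      if f is not None and f.d_app > 0])
    return tlog, np.log10(cvals)
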