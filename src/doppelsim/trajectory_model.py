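"""Trajectory data model, tabular I/O, filtering, and experiment-ledger extraction.

Canonical units are nanometers and milliseconds everywhere; unit conversion
happens only at I/O boundaries (the ``mosaic`` dialect).  Coordinates are
referenced to one cell corner with x along the long axis, so the cell
interior is ``[0, L] x [0, W]``; experimental tracks need not be registered
to a cell box — only the simulator uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "CellRecord",
    "TrackSet",
    "ExperimentStats",
    "TrackFormatError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "filter_min_length",
    "extract_experiment_stats",
    "step_lengths",
]

#: Canonical column order for the plain-text track table.
TRACK_COLUMNS = ["track_id", "cell_id", "session_id", "day_id", "frame", "x_nm", "y_nm"]
CELL_COLUMNS = ["cell_id", "session_id", "day_id", "length_nm", "width_nm"]

DEFAULT_FRAME_INTERVAL_MS = 10.0
DEFAULT_MIN_TRACK_POINTS = 10


class TrackFormatError(ValueError):
    """Raised when an input table is missing required structure."""


class TrackValidationError(ValueError):
    """Raised when track contents violate model invariants (e.g. frame gaps)."""


@dataclass(frozen=True)
class Track:
    """One particle trajectory: (x, y) positions at consecutive frames."""

    track_id: str
    cell_id: str
    session_id: str
    day_id: str
    frame_interval: float  # ms
    positions: np.ndarray  # shape (n_points, 2), nm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise TrackValidationError(
                f"track {self.track_id}: positions must be (n, 2), got {pos.shape}"
            )
        if pos.shape[0] < 1:
            raise TrackValidationError(f"track {self.track_id}: empty track")
        if not np.all(np.isfinite(pos)):
            raise TrackValidationError(f"track {self.track_id}: non-finite coordinate")
        if self.frame_interval <= 0:
            raise TrackValidationError(
                f"track {self.track_id}: frame_interval must be > 0"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def duration_ms(self) -> float:
        return (self.n_points - 1) * self.frame_interval


@dataclass(frozen=True)
class CellRecord:
    """Geometry and provenance of one cell (long axis L, short axis W, nm)."""

    cell_id: str
    session_id: str
    day_id: str
    length_L: float  # nm
    width_W: float  # nm
    empty_after_filter: bool = False

    def __post_init__(self) -> None:
        if self.length_L <= 0 or self.width_W <= 0:
            raise TrackValidationError(
                f"cell {self.cell_id}: non-positive dimensions "
                f"L={self.length_L}, W={self.width_W}"
            )


@dataclass
class TrackSet:
    """A collection of tracks with their cell records and free-text provenance."""

    tracks: list[Track]
    cells: list[CellRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {c.cell_id: c for c in self.cells}
        if len(by_id) != len(self.cells):
            raise TrackValidationError("duplicate cell_id in cell records")
        for tr in self.tracks:
            cell = by_id.get(tr.cell_id)
            if cell is None:
                raise TrackValidationError(
                    f"track {tr.track_id}: unknown cell_id {tr.cell_id!r}"
                )
            if (tr.session_id, tr.day_id) != (cell.session_id, cell.day_id):
                raise TrackValidationError(
                    f"track {tr.track_id}: session/day labels disagree with "
                    f"cell {tr.cell_id}"
                )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def tracks_by_cell(self) -> dict[str, list[Track]]:
        out: dict[str, list[Track]] = {c.cell_id: [] for c in self.cells}
        for tr in self.tracks:
            out[tr.cell_id].append(tr)
        return out

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


@dataclass(frozen=True)
class CellStats:
    """Ledger entry for one cell: geometry plus its track durations (frames)."""

    cell_id: str
    session_id: str
    day_id: str
    length_L: float
    durations: tuple[int, ...]  # n_points per track, ledger order


@dataclass(frozen=True)
class ExperimentStats:
    """The Doppelgänger ledger: exactly what a simulation must replicate.

    One entry per cell carrying the cell length and the list of per-track
    durations (in frames); the companion simulation produces one cell per
    entry and one track per duration.
    """

    cells: tuple[CellStats, ...]
    frame_interval: float  # ms

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be > 0")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_tracks(self) -> int:
        return sum(len(c.durations) for c in self.cells)

    @property
    def max_duration(self) -> int:
        return max((max(c.durations) for c in self.cells if c.durations), default=0)


# ---------------------------------------------------------------------------
# I/O


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{what}: missing required column(s) {missing}")


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    return "\t" if "\t" in header else ","


def read_tracks(
    path,
    dialect: str = "canonical",
    cells_path=None,
    *,
    frame_interval_ms: float | None = None,
    pixel_size_nm: float | None = None,
) -> TrackSet:
    """Read a plain-text track table into a :class:`TrackSet`.

    ``canonical`` expects columns ``track_id, cell_id, session_id, day_id,
    frame, x_nm, y_nm`` (tab or comma separated) with nm/ms units.  ``mosaic``
    accepts a MOSAIC-ParticleTracker-style per-trajectory table with columns
    ``Trajectory, Frame, x, y`` in pixels; ``pixel_size_nm`` and
    ``frame_interval_ms`` are then mandatory (the upstream convention is not
    standardized, so conversions are never guessed).

    A companion cell table (``cells_path``) supplies cell geometry; without
    one, placeholder cells spanning the observed track extents are created.
    """
    if dialect not in ("canonical", "mosaic"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == "mosaic":
        if pixel_size_nm is None or frame_interval_ms is None:
            raise TrackFormatError(
                "mosaic dialect requires explicit pixel_size_nm and "
                "frame_interval_ms (no defaults are assumed)"
            )
        df = pd.read_csv(path, sep=None, engine="python")
        _require_columns(df, ["Trajectory", "Frame", "x", "y"], "mosaic table")
        df = pd.DataFrame(
            {
                "track_id": df["Trajectory"].astype(str),
                "cell_id": df.get("cell_id", pd.Series(["cell0"] * len(df))).astype(str),
                "session_id": df.get("session_id", pd.Series(["s0"] * len(df))).astype(str),
                "day_id": df.get("day_id", pd.Series(["d0"] * len(df))).astype(str),
                "frame": df["Frame"].astype(int),
                "x_nm": df["x"].astype(float) * pixel_size_nm,
                "y_nm": df["y"].astype(float) * pixel_size_nm,
            }
        )
        dt = float(frame_interval_ms)
    else:
        df = pd.read_csv(path, sep=_detect_sep(path), comment="#",
                         float_precision="round_trip")
        _require_columns(df, TRACK_COLUMNS, "canonical track table")
        dt = float(frame_interval_ms) if frame_interval_ms else DEFAULT_FRAME_INTERVAL_MS

    extra_cols = [c for c in df.columns if c not in TRACK_COLUMNS]

    tracks: list[Track] = []
    seen_cells: dict[str, tuple[str, str]] = {}
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise TrackValidationError(
                f"track {tid}: frames are not consecutive (gap or duplicate)"
            )
        cell_id = str(g["cell_id"].iloc[0])
        session_id = str(g["session_id"].iloc[0])
        day_id = str(g["day_id"].iloc[0])
        seen_cells.setdefault(cell_id, (session_id, day_id))
        tracks.append(
            Track(
                track_id=str(tid),
                cell_id=cell_id,
                session_id=session_id,
                day_id=day_id,
                frame_interval=dt,
                positions=g[["x_nm", "y_nm"]].to_numpy(dtype=float),
            )
        )

    if cells_path is not None:
        cdf = pd.read_csv(cells_path, sep=_detect_sep(cells_path))
        _require_columns(cdf, CELL_COLUMNS, "cell table")
        cells = [
            CellRecord(
                cell_id=str(r.cell_id),
                session_id=str(r.session_id),
                day_id=str(r.day_id),
                length_L=float(r.length_nm),
                width_W=float(r.width_nm),
            )
            for r in cdf.itertuples()
        ]
    else:
        cells = [
            CellRecord(cid, sess, day, length_L=1.0e4, width_W=3.0e3)
            for cid, (sess, day) in seen_cells.items()
        ]

    prov = {"source": str(path), "dialect": dialect}
    if extra_cols:
        prov["extra_columns"] = {c: df[c].tolist() for c in extra_cols}
    return TrackSet(tracks=tracks, cells=cells, provenance=prov)


def write_tracks(ts: TrackSet, path, cells_path=None, sep: str = "\t") -> None:
    """Write a TrackSet as a canonical track table (losslessly round-trippable)."""
    rows = []
    for tr in ts.tracks:
        for i in range(tr.n_points):
            rows.append(
                (tr.track_id, tr.cell_id, tr.session_id, tr.day_id, i,
                 tr.positions[i, 0], tr.positions[i, 1])
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    # repr-level float formatting keeps the round trip bit-exact
    df.to_csv(path, sep=sep, index=False, float_format=lambda v: repr(float(v)))
    if cells_path is not None:
        cdf = pd.DataFrame(
            [(c.cell_id, c.session_id, c.day_id, c.length_L, c.width_W) for c in ts.cells],
            columns=CELL_COLUMNS,
        )
        cdf.to_csv(cells_path, sep=sep, index=False,
                   float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Filtering and ledger extraction


def filter_min_length(ts: TrackSet, min_points: int = DEFAULT_MIN_TRACK_POINTS) -> TrackSet:
    """Drop tracks with fewer than ``min_points`` positions.

    Cells left with zero tracks are retained but flagged so that cell-wise
    bookkeeping stays one-to-one with the original set.  Idempotent.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    surviving = [tr for tr in ts.tracks if tr.n_points >= min_points]
    alive = {tr.cell_id for tr in surviving}
    cells = [
        c if c.cell_id in alive else CellRecord(
            c.cell_id, c.session_id, c.day_id, c.length_L, c.width_W,
            empty_after_filter=True,
        )
        for c in ts.cells
    ]
    return TrackSet(tracks=surviving, cells=cells, provenance=dict(ts.provenance))


def extract_experiment_stats(ts: TrackSet) -> ExperimentStats:
    """Extract the Doppelgänger ledger (cell lengths + per-track durations)."""
    dt = ts.tracks[0].frame_interval if ts.tracks else DEFAULT_FRAME_INTERVAL_MS
    by_cell = ts.tracks_by_cell()
    entries = tuple(
        CellStats(
            cell_id=c.cell_id,
            session_id=c.session_id,
            day_id=c.day_id,
            length_L=c.length_L,
            durations=tuple(tr.n_points for tr in by_cell[c.cell_id]),
        )
        for c in ts.cells
    )
    return ExperimentStats(cells=entries, frame_interval=dt)


def step_lengths(ts: TrackSet) -> np.ndarray:
    """All per-frame 2D displacement magnitudes (nm), pooled over tracks."""
    if not ts.tracks:
        raise ValueError("empty TrackSet")
    chunks = [
        np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        for tr in ts.tracks
        if tr.n_points >= 2
    ]
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# Ledger I/O (plain-text, used by the CLI)


def write_experiment_stats(stats: ExperimentStats, path, sep: str = "\t") -> None:
    rows = [
        (c.cell_id, c.session_id, c.day_id, c.length_L,
         ",".join(map(str, c.durations)))
        for c in stats.cells
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "session_id", "day_id",
                                     "length_nm", "durations_frames"])
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_ms={stats.frame_interval!r}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=lambda v: repr(float(v)))


def read_experiment_stats(path) -> ExperimentStats:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# frame_interval_ms="):
            raise TrackFormatError("ledger file missing frame_interval header")
        dt = float(first.split("=", 1)[1])
        # dtype=str + explicit float() keeps length_nm bit-exact on round trips
        df = pd.read_csv(fh, sep=None, engine="python", dtype=str)
    _require_columns(df, ["cell_id", "session_id", "day_id", "length_nm",
                          "durations_frames"], "ledger table")
    cells = tuple(
        CellStats(
            cell_id=str(r.cell_id),
            session_id=str(r.session_id),
            day_id=str(r.day_id),
            length_L=float(r.length_nm),
            durations=tuple(
                int(d) for d in str(r.durations_frames).split(",") if d != "" and d != "nan"
            ),
        )
        for r in df.itertuples()
    )
    return ExperimentStats(cells=cells, frame_interval=dt)
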