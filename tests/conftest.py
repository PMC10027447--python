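import numpy as np
import pytest

from doppelsim import (
    ModelConfig,
    SynthConfig,
    Track,
    TrackSet,
    generate_experiment_stats,
    run_doppelganger,
)
from doppelsim.trajectory_model import CellRecord


def make_track(positions, track_id="t0", cell_id="c0", session_id="s0",
               day_id="d0", dt=10.0):
    return Track(track_id=track_id, cell_id=cell_id, session_id=session_id,
                 day_id=day_id, frame_interval=dt,
                 positions=np.asarray(positions, dtype=float))


def make_cell(cell_id="c0", session_id="s0", day_id="d0", L=10_000.0, W=3_000.0):
    return CellRecord(cell_id=cell_id, session_id=session_id, day_id=day_id,
                      length_L=L, width_W=W)


@pytest.fixture
def tiny_trackset():
    """Three tracks in two cells, deterministic positions."""
    rng = np.random.default_rng(42)
    tracks = [
        make_track(rng.normal(5000, 100, (12, 2)), "t0", "c0"),
        make_track(rng.normal(5000, 100, (20, 2)), "t1", "c0"),
        make_track(rng.normal(5000, 100, (15, 2)), "t2", "c1", "s1", "d1"),
    ]
    cells = [make_cell("c0"), make_cell("c1", "s1", "d1")]
    return TrackSet(tracks=tracks, cells=cells)


@pytest.fixture(scope="session")
def small_ledger():
    """A 20-cell synthetic ledger for module-level simulation tests."""
    return generate_experiment_stats(SynthConfig(n_cells=20, seed=7))


@pytest.fixture(scope="session")
def full_ledger():
    """The full-scale synthetic ledger (145 cells)."""
    return generate_experiment_stats(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def uniform_sim(full_ledger):
    """A uniform-model simulation of the full ledger (shared: it is the
    most expensive fixture several acceptance criteria rely on)."""
    return run_doppelganger(full_ledger, ModelConfig(model="uniform", seed=4))
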