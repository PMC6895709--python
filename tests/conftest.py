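
import pandas as pd
import pytest

from swifi.simulate import (
    CameraModel,
    OpticsModel,
    PhotophysicsModel,
    SimulationConfig,
    simulate_movie,
)


def loc_frame(rows):
    """Minimal localization table from (frame, x, y) tuples."""
    return pd.DataFrame(
        [(f, "donor", "D", x, y, 1000.0, 10, 0.0) for f, x, y in rows],
        columns=["frame", "channel", "excitation", "x_px", "y_px",
                 "intensity", "area", "background"],
    )


def track_frame(points):
    """Track table from (track_id, frame, x, y) tuples."""
    return pd.DataFrame(points, columns=["track_id", "frame", "x_px", "y_px"])


@pytest.fixture(scope="session")
def small_movie():
    """A modest two-channel movie with moderate diffusion, with truth."""
    cfg = SimulationConfig(
        n_emitters_mean=10, fov_px=(64, 64), d_um2_s=(2.0,),
        frame_time_ms=20.0, n_frames=120, seed=1234,
    )
    photo = PhotophysicsModel(photon_rate_per_ms=300.0, e_states=(0.45,))
    movie, truth = simulate_movie(cfg, photophysics=photo)
    return movie, truth


@pytest.fixture(scope="session")
def stationary_movie():
    """Bright immobile emitters: localization accuracy test bed."""
    cfg = SimulationConfig(
        n_emitters_mean=6, fov_px=(64, 64), d_um2_s=(0.0,),
        frame_time_ms=10.0, n_frames=80, seed=99, slab_z_um=0.4,
    )
    photo = PhotophysicsModel(photon_rate_per_ms=300.0)
    movie, truth = simulate_movie(cfg, photophysics=photo)
    return movie, truth
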