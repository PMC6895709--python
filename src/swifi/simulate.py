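"""Synthetic two-channel single-molecule movies with known ground truth.

The simulator emulates freely diffusing fluorescent emitters imaged on a
wide-field microscope whose thin effective observation depth is set by
the axial point-spread function: emitters perform 3D Brownian motion in
a slab, their detected brightness is weighted by an axial Gaussian
profile, and each camera frame integrates many substeps of motion so
that fast molecules are rendered with realistic motion blur.  Donor and
acceptor emission is partitioned by a (possibly switching) FRET
efficiency and the two channels are written side by side on one chip,
optionally under alternating-laser (ALEX) excitation.

Every stochastic element is driven by one seeded generator, so a given
configuration reproduces bit-identical movies, and the full ground
truth (substep trajectories, photophysical states, per-frame true
centroids and photon counts) is returned alongside the movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .movie import ChannelLayout, Movie

__all__ = [
    "SimulationConfig",
    "OpticsModel",
    "PhotophysicsModel",
    "CameraModel",
    "EmissionStates",
    "GroundTruth",
    "alex_schedule",
    "constant_schedule",
    "draw_trajectories",
    "evolve_photophysics",
    "render_movie",
    "simulate_movie",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Geometry, diffusion and timing of a synthetic acquisition.

    ``d_um2_s`` lists one diffusion coefficient per species and
    ``species_weights`` their mixture weights.  The simulated box is
    laterally larger than the imaged field of view by ``margin_um`` on
    every side, so that emitters can wander in and out of the field;
    axially the emitters live in a slab of thickness ``slab_z_um``
    centred on the focal plane, with reflecting faces.
    """

    n_emitters_mean: float = 15.0
    fov_px: tuple[int, int] = (128, 128)  # (ny, nx) of one channel
    margin_um: float = 1.5
    slab_z_um: float = 3.0
    d_um2_s: tuple[float, ...] = (10.0,)
    species_weights: tuple[float, ...] = (1.0,)
    frame_time_ms: float = 10.0
    n_substeps: int = 20
    n_frames: int = 100
    pixel_size_nm: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.d_um2_s, dtype=float))
        w = np.atleast_1d(np.asarray(self.species_weights, dtype=float))
        if np.any(d < 0):
            raise ConfigurationError("negative diffusion coefficient")
        if len(d) != len(w):
            raise ConfigurationError("species weights do not match D list")
        if not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("species weights must sum to 1")
        if self.frame_time_ms <= 0:
            raise ConfigurationError("frame_time_ms must be positive")
        if self.n_substeps < 10:
            raise ConfigurationError("n_substeps must be at least 10")
        if self.pixel_size_nm <= 0 or self.slab_z_um <= 0:
            raise ConfigurationError("pixel size and slab depth must be positive")
        self.d_um2_s = tuple(float(v) for v in d)
        self.species_weights = tuple(float(v) for v in w)

    @property
    def pixel_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def fov_um(self) -> tuple[float, float]:
        ny, nx = self.fov_px
        return ny * self.pixel_um, nx * self.pixel_um

    @property
    def box_um(self) -> tuple[float, float]:
        """Lateral extent (y, x) of the simulated box in micrometres."""
        fy, fx = self.fov_um
        return fy + 2 * self.margin_um, fx + 2 * self.margin_um

    @property
    def substep_s(self) -> float:
        return self.frame_time_ms / 1000.0 / self.n_substeps

    @property
    def total_substeps(self) -> int:
        return self.n_frames * self.n_substeps


@dataclass
class OpticsModel:
    """Lateral PSF, axial detection profile and channel geometry."""

    psf_sigma_lateral_nm: float = 110.0
    axial_fwhm_nm: float = 610.0
    channel_offset_px: tuple[float, float] = (0.0, 0.0)
    crosstalk: float = 0.0

    def __post_init__(self) -> None:
        if self.axial_fwhm_nm <= 0:
            raise ConfigurationError("axial_fwhm_nm must be positive")
        if not 0 <= self.crosstalk < 1:
            raise ConfigurationError("crosstalk must be in [0, 1)")

    @property
    def axial_sigma_um(self) -> float:
        return self.axial_fwhm_nm * _FWHM_TO_SIGMA / 1000.0


@dataclass
class PhotophysicsModel:
    """Emission rate, FRET states, switching, dark acceptors, bleaching.

    ``e_states`` lists FRET efficiencies; ``switch_rates`` gives each
    state's exit rate in 1/s (a continuous-time Markov chain jumping
    uniformly to the other states).  A fraction of emitters starts with
    an inactive (dark) acceptor, which forces apparent E = 0.  Bleached
    states are absorbing.
    """

    photon_rate_per_ms: float = 200.0
    e_states: tuple[float, ...] = (0.0,)
    switch_rates_per_s: tuple[float, ...] = (0.0,)
    acceptor_inactive_fraction: float = 0.0
    bleach_rate_donor_per_s: float = 0.0
    bleach_rate_acceptor_per_s: float = 0.0

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.e_states, dtype=float))
        k = np.atleast_1d(np.asarray(self.switch_rates_per_s, dtype=float))
        if np.any((e < 0) | (e > 1)):
            raise ConfigurationError("FRET efficiencies must lie in [0, 1]")
        if len(k) != len(e):
            raise ConfigurationError("switch_rates must match e_states")
        if np.any(k < 0) or self.bleach_rate_donor_per_s < 0 \
                or self.bleach_rate_acceptor_per_s < 0:
            raise ConfigurationError("rates must be non-negative")
        if not 0 <= self.acceptor_inactive_fraction <= 1:
            raise ConfigurationError("acceptor_inactive_fraction in [0, 1]")
        if self.photon_rate_per_ms < 0:
            raise ConfigurationError("photon rate must be non-negative")
        self.e_states = tuple(float(v) for v in e)
        self.switch_rates_per_s = tuple(float(v) for v in k)


@dataclass
class CameraModel:
    """Additive-noise camera: Poisson shot noise, Gaussian read noise."""

    read_noise_sd: float = 1.6
    gain: float = 2.0
    offset: float = 100.0
    quantum_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ConfigurationError("read_noise_sd must be non-negative")
        if self.gain <= 0:
            raise ConfigurationError("gain must be positive")
        if not 0 < self.quantum_efficiency <= 1:
            raise ConfigurationError("quantum_efficiency in (0, 1]")


@dataclass
class EmissionStates:
    """Per-substep photophysical state of every emitter."""

    fret_idx: np.ndarray      # (n_emitters, total_substeps) int8
    donor_on: np.ndarray      # (n_emitters, total_substeps) bool
    acceptor_on: np.ndarray   # (n_emitters, total_substeps) bool
    e_states: tuple[float, ...]
    photon_rate_per_ms: float = 200.0

    @property
    def e_eff(self) -> np.ndarray:
        """Effective FRET efficiency per substep (0 when acceptor dark)."""
        e = np.asarray(self.e_states)[self.fret_idx]
        return np.where(self.acceptor_on, e, 0.0)


@dataclass
class GroundTruth:
    """Everything the simulator knows about the movie it rendered."""

    config: SimulationConfig
    xyz_um: np.ndarray                 # (n_emitters, total_substeps, 3), boxed
    species: np.ndarray                # (n_emitters,) index into d_um2_s
    xyz_free_um: np.ndarray | None = None  # unbounded walk (for step statistics)
    states: EmissionStates | None = None
    frame_xy_px: np.ndarray | None = None      # (n_emitters, n_frames, 2)
    frame_photons: np.ndarray | None = None    # (n_emitters, n_frames, 2)
    excitation: np.ndarray | None = None

    @property
    def n_emitters(self) -> int:
        return self.xyz_um.shape[0]

    def lateral_px(self) -> np.ndarray:
        """Substep (x, y) in donor-channel pixel coordinates."""
        cfg = self.config
        by, bx = cfg.box_um
        x = (self.xyz_um[:, :, 0] - (bx - cfg.fov_um[1]) / 2) / cfg.pixel_um
        y = (self.xyz_um[:, :, 1] - (by - cfg.fov_um[0]) / 2) / cfg.pixel_um
        return np.stack([x, y], axis=-1) - 0.5
        # -0.5: pixel centres sit at integer coordinates

    def to_frame(self) -> pd.DataFrame:
        """Long-form ground-truth table (one row per emitter substep)."""
        cfg = self.config
        n, t = self.n_emitters, cfg.total_substeps
        idx = np.arange(t)
        rows = {
            "emitter_id": np.repeat(np.arange(n), t),
            "frame": np.tile(idx // cfg.n_substeps, n),
            "substep": np.tile(idx % cfg.n_substeps, n),
            "x_nm": (self.xyz_um[:, :, 0] * 1000).ravel(),
            "y_nm": (self.xyz_um[:, :, 1] * 1000).ravel(),
            "z_nm": (self.xyz_um[:, :, 2] * 1000).ravel(),
        }
        if self.states is not None:
            state = np.where(
                self.states.donor_on,
                np.where(self.states.acceptor_on, self.states.fret_idx, -1),
                -2,
            )
            rows["state"] = state.ravel()
        return pd.DataFrame(rows)


def alex_schedule(n_frames: int, phase: int = 0, period: int = 1) -> np.ndarray:
    """Alternating-laser excitation labels, one per frame.

    With the default phase, even frames are donor-excited ("D") and odd
    frames acceptor-excited ("A"); ``phase=1`` starts on "A".  ``period``
    frames are acquired per laser before switching.
    """
    if n_frames < 0 or period < 1:
        raise ValueError("n_frames >= 0 and period >= 1 required")
    i = np.arange(n_frames) // period + phase
    return np.where(i % 2 == 0, "D", "A")


def constant_schedule(n_frames: int, label: str = "D") -> np.ndarray:
    """Continuous-wave excitation: every frame carries the same label."""
    if label not in ("D", "A"):
        raise ValueError("label must be 'D' or 'A'")
    return np.full(n_frames, label)


def draw_trajectories(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Simulate 3D Brownian trajectories at substep resolution.

    Each emitter takes independent Gaussian steps with per-axis standard
    deviation ``sqrt(2 D dt)`` where ``dt`` is the substep duration.
    The axial coordinate reflects off the slab faces.  Lateral
    coordinates wrap periodically at the box faces, which emulates the
    replenishment of a practically infinite reservoir: a molecule
    leaving one side re-enters on the opposite side, far outside the
    tracker's gating radius, and is indistinguishable from a fresh
    molecule.  This keeps the emitter density stationary over
    arbitrarily long movies without distorting interior step statistics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(rng.poisson(config.n_emitters_mean)) if config.n_emitters_mean > 0 else 0
    species = rng.choice(
        len(config.d_um2_s), size=n, p=np.asarray(config.species_weights)
    )
    d = np.asarray(config.d_um2_s)[species]          # (n,)
    t = config.total_substeps
    by, bx = config.box_um
    half_z = config.slab_z_um / 2.0

    start = np.empty((n, 3))
    start[:, 0] = rng.uniform(0, bx, n)
    start[:, 1] = rng.uniform(0, by, n)
    start[:, 2] = rng.uniform(-half_z, half_z, n)

    sigma = np.sqrt(2.0 * d * config.substep_s)       # (n,)
    steps = rng.standard_normal((n, t - 1, 3)) * sigma[:, None, None] \
        if t > 1 else np.zeros((n, 0, 3))
    xyz = np.concatenate([start[:, None, :], steps], axis=1).cumsum(axis=1)
    free = xyz.copy()

    # reflect z off the slab faces (fold the free walk into the slab)
    z = xyz[:, :, 2] + half_z
    period = 2.0 * config.slab_z_um
    z = np.abs(np.mod(z + config.slab_z_um, period) - config.slab_z_um)
    xyz[:, :, 2] = z - half_z
    # periodic lateral wrap (reservoir replenishment)
    xyz[:, :, 0] = np.mod(xyz[:, :, 0], bx)
    xyz[:, :, 1] = np.mod(xyz[:, :, 1], by)

    return GroundTruth(config=config, xyz_um=xyz, species=species,
                       xyz_free_um=free)


def evolve_photophysics(
    truth: GroundTruth,
    model: PhotophysicsModel,
    rng: np.random.Generator | None = None,
) -> EmissionStates:
    """Sample every emitter's photophysical state at substep resolution.

    FRET-state switching is a continuous-time Markov chain sampled on
    the substep grid; donor/acceptor bleaching are absorbing exponential
    clocks; a fraction of emitters starts with a dark acceptor.
    """
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    n, t = truth.n_emitters, truth.config.total_substeps
    dt = truth.config.substep_s
    n_states = len(model.e_states)

    fret = np.zeros((n, t), dtype=np.int8)
    k = np.asarray(model.switch_rates_per_s)
    if n_states > 1:
        # initial state from the chain's stationary distribution
        q = np.zeros((n_states, n_states))
        for i in range(n_states):
            if k[i] > 0:
                q[i, :] = k[i] / (n_states - 1)
                q[i, i] = -k[i]
        if np.any(k > 0):
            # stationary vector: solve pi Q = 0, sum(pi) = 1
            a = np.vstack([q.T, np.ones(n_states)])
            b = np.zeros(n_states + 1)
            b[-1] = 1.0
            pi = np.linalg.lstsq(a, b, rcond=None)[0]
            pi = np.clip(pi, 0, None)
            pi /= pi.sum()
        else:
            pi = np.full(n_states, 1.0 / n_states)
        state = rng.choice(n_states, size=n, p=pi).astype(np.int8)
        fret[:, 0] = state
        if np.any(k > 0):
            p_exit = 1.0 - np.exp(-k * dt)
            for j in range(1, t):
                u = rng.random(n)
                jump = u < p_exit[state]
                if np.any(jump):
                    if n_states == 2:
                        state = np.where(jump, 1 - state, state).astype(np.int8)
                    else:
                        shift = rng.integers(1, n_states, size=n)
                        state = np.where(
                            jump, (state + shift) % n_states, state
                        ).astype(np.int8)
                fret[:, j] = state
        else:
            fret[:] = state[:, None]

    sub = np.arange(t)

    def _alive(rate: float) -> np.ndarray:
        if rate <= 0:
            return np.ones((n, t), dtype=bool)
        p = 1.0 - np.exp(-rate * dt)
        life = rng.geometric(p, size=n)  # substeps survived
        return sub[None, :] < life[:, None]

    donor_on = _alive(model.bleach_rate_donor_per_s)
    acceptor_on = _alive(model.bleach_rate_acceptor_per_s)
    dark = rng.random(n) < model.acceptor_inactive_fraction
    acceptor_on[dark, :] = False

    states = EmissionStates(
        fret_idx=fret, donor_on=donor_on, acceptor_on=acceptor_on,
        e_states=model.e_states,
        photon_rate_per_ms=model.photon_rate_per_ms,
    )
    truth.states = states
    return states


def _deposit_gaussians(
    acc: np.ndarray,
    frame_idx: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    photons: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Add integrated-Gaussian spots to ``acc``; return photons deposited.

    ``acc`` is (n_frames, ny, nx); coordinates follow the pixel-centre
    convention (pixel (i, j) spans [j-0.5, j+0.5) x [i-0.5, i+0.5)).
    """
    n_frames, ny, nx = acc.shape
    r = int(np.ceil(4.0 * sigma_px)) + 1
    s = sigma_px * np.sqrt(2.0)
    deposited = np.zeros(len(x))
    for m in range(len(x)):
        cx, cy, p = x[m], y[m], photons[m]
        j0 = max(int(np.floor(cx)) - r, 0)
        j1 = min(int(np.floor(cx)) + r + 1, nx)
        i0 = max(int(np.floor(cy)) - r, 0)
        i1 = min(int(np.floor(cy)) + r + 1, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        jj = np.arange(j0, j1)
        ii = np.arange(i0, i1)
        gx = 0.5 * (erf((jj + 0.5 - cx) / s) - erf((jj - 0.5 - cx) / s))
        gy = 0.5 * (erf((ii + 0.5 - cy) / s) - erf((ii - 0.5 - cy) / s))
        patch = p * np.outer(gy, gx)
        acc[frame_idx[m], i0:i1, j0:j1] += patch
        deposited[m] = patch.sum()
    return deposited


def render_movie(
    truth: GroundTruth,
    states: EmissionStates | None,
    optics: OpticsModel,
    camera: CameraModel,
    excitation: np.ndarray | None = None,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> Movie:
    """Render the camera movie for a set of trajectories and states.

    Per substep each emitting molecule deposits an integrated 2D
    Gaussian at its lateral position, scaled by the axial Gaussian
    detection weight; a frame is the sum of its substeps (motion blur).
    Under donor excitation the photons split between the channels as
    ``(1-E)(1-ct)`` (donor) and ``E + ct (1-E)`` (acceptor); under
    acceptor excitation only active acceptors emit, into the acceptor
    channel.  Camera counts are ``Poisson(photons) * gain + read noise
    + offset`` (noise omitted entirely when ``noise=False``, in which
    case the expected image is returned as floats).
    """
    cfg = truth.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if excitation is None:
        excitation = constant_schedule(cfg.n_frames)
    excitation = np.asarray(excitation)
    if len(excitation) != cfg.n_frames:
        raise ValueError("excitation schedule length != n_frames")
    if states is None:
        states = EmissionStates(
            fret_idx=np.zeros((truth.n_emitters, cfg.total_substeps), np.int8),
            donor_on=np.ones((truth.n_emitters, cfg.total_substeps), bool),
            acceptor_on=np.ones((truth.n_emitters, cfg.total_substeps), bool),
            e_states=(0.0,),
        )

    n, t = truth.n_emitters, cfg.total_substeps
    ny, nx = cfg.fov_px
    dt_ms = cfg.frame_time_ms / cfg.n_substeps
    # photons detected per substep for an in-focus emitter
    per_substep = states.photon_rate_per_ms * camera.quantum_efficiency * dt_ms

    w = np.exp(
        -truth.xyz_um[:, :, 2] ** 2 / (2.0 * optics.axial_sigma_um ** 2)
    )
    base = per_substep * w  # (n, t)

    e_eff = states.e_eff
    donor_exc = np.repeat(excitation == "D", cfg.n_substeps)  # (t,)
    ct = optics.crosstalk

    # photon budget per (emitter, substep, channel)
    ph_d = np.where(
        donor_exc[None, :] & states.donor_on, base * (1.0 - e_eff) * (1.0 - ct), 0.0
    )
    ph_a = np.where(
        donor_exc[None, :] & states.donor_on,
        base * (e_eff + ct * (1.0 - e_eff)),
        0.0,
    )
    ph_a = ph_a + np.where(
        (~donor_exc[None, :]) & states.acceptor_on, base, 0.0
    )
    del base

    lateral = truth.lateral_px()            # (n, t, 2)
    frame_of = np.tile(
        np.repeat(np.arange(cfg.n_frames), cfg.n_substeps), (n, 1)
    )
    sigma_px = optics.psf_sigma_lateral_nm / cfg.pixel_size_nm
    off_x, off_y = optics.channel_offset_px

    channels = np.zeros((2, cfg.n_frames, ny, nx))
    frame_photons = np.zeros((n, cfg.n_frames, 2))
    if truth.n_emitters:
        for ci, (ph, dx, dy) in enumerate(
            [(ph_d, 0.0, 0.0), (ph_a, off_x, off_y)]
        ):
            mask = ph > 1e-6
            if not np.any(mask):
                continue
            em, ss = np.where(mask)
            dep = _deposit_gaussians(
                channels[ci],
                frame_of[em, ss],
                lateral[em, ss, 0] + dx,
                lateral[em, ss, 1] + dy,
                ph[em, ss],
                sigma_px,
            )
            np.add.at(frame_photons, (em, frame_of[em, ss], ci), dep)

        # photon-weighted true frame centroid (donor-channel coordinates)
        tot = ph_d + ph_a                                 # (n, t)
        wsum = np.zeros((n, cfg.n_frames))
        wx = np.zeros((n, cfg.n_frames))
        wy = np.zeros((n, cfg.n_frames))
        fo = frame_of[0]
        for f in range(cfg.n_frames):
            sl = slice(f * cfg.n_substeps, (f + 1) * cfg.n_substeps)
            wsum[:, f] = tot[:, sl].sum(axis=1)
            wx[:, f] = (tot[:, sl] * lateral[:, sl, 0]).sum(axis=1)
            wy[:, f] = (tot[:, sl] * lateral[:, sl, 1]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            truth.frame_xy_px = np.stack([wx / wsum, wy / wsum], axis=-1)
    else:
        truth.frame_xy_px = np.zeros((0, cfg.n_frames, 2))
    truth.frame_photons = frame_photons
    truth.excitation = excitation

    if np.any(channels * camera.gain > 2 ** 31):
        raise OverflowError("photon budget overflows 31-bit counts")

    frames = np.concatenate([channels[0], channels[1]], axis=2)
    if noise:
        counts = rng.poisson(frames).astype(np.float64) * camera.gain
        counts += rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
        counts += camera.offset
        data = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    else:
        data = frames * camera.gain + camera.offset

    return Movie(
        data=data,
        pixel_size_nm=cfg.pixel_size_nm,
        frame_time_ms=cfg.frame_time_ms,
        excitation=excitation,
        layout=ChannelLayout(channel_offset=tuple(optics.channel_offset_px)),
        seed=cfg.seed,
    )


def simulate_movie(
    config: SimulationConfig,
    optics: OpticsModel | None = None,
    photophysics: PhotophysicsModel | None = None,
    camera: CameraModel | None = None,
    excitation: np.ndarray | str | None = None,
    noise: bool = True,
) -> tuple[Movie, GroundTruth]:
    """End-to-end convenience wrapper: trajectories, states, rendering.

    ``excitation`` may be an explicit per-frame label array, "alex" for
    the default donor/acceptor alternation, or None for continuous
    donor excitation.
    """
    optics = optics or OpticsModel()
    photophysics = photophysics or PhotophysicsModel()
    camera = camera or CameraModel()
    rng = np.random.default_rng(config.seed)
    truth = draw_trajectories(config, rng)
    states = evolve_photophysics(truth, photophysics, rng)
    if isinstance(excitation, str):
        if excitation != "alex":
            raise ValueError("excitation string must be 'alex'")
        excitation = alex_schedule(config.n_frames)
    movie = render_movie(
        truth,
        states,
        optics,
        camera,
        excitation=excitation,
        noise=noise,
        rng=rng,
    )
    return movie, truth
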