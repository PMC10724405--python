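"""Event-driven hard-sphere dynamics: configuration, state, and drivers.

Reduced units throughout: lengths in multiples of the reference diameter
``sigma``, masses in multiples of the reference mass ``m``, temperature
``k_B T = 1`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ..composition import SpeciesSet, packing_fraction, realize_counts
from . import _kernels as K

__all__ = [
    "SimConfig",
    "SimState",
    "EventRecord",
    "Frames",
    "JammingError",
    "EngineError",
    "predict_pair_collision",
    "resolve_collision",
    "thermostat_event",
    "initial_state",
    "compress_to_phi",
    "run",
    "equilibrate",
    "sample_frames",
    "simulate",
]


class EngineError(RuntimeError):
    """Internal inconsistency detected while processing events."""


class JammingError(RuntimeError):
    """Compression could not reach the target packing fraction."""

    def __init__(self, achieved_phi: float, target_phi: float):
        self.achieved_phi = achieved_phi
        self.target_phi = target_phi
        super().__init__(
            f"jammed at phi={achieved_phi:.4f} before reaching target {target_phi:.4f}"
        )


@dataclass
class SimConfig:
    """Run parameters for a hard-sphere simulation.

    ``thermostat_rate`` is the ghost-collision (velocity-resampling) rate
    per particle per reduced time; ``growth_rate`` the fractional diameter
    growth per reduced time used during compression.  ``restitution`` is
    the normal restitution coefficient (1 = elastic).
    """

    n_particles: int
    species_set: SpeciesSet
    target_phi: float
    temperature: float = 1.0
    restitution: float = 1.0
    thermostat_rate: float = 0.1
    growth_rate: float = 0.02
    seed: int = 0
    equilibration_collisions_per_particle: int = 100
    phi_init: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.target_phi < 0.64:
            raise ValueError(f"target_phi must lie in (0, 0.64), got {self.target_phi}")
        if not 0.0 < self.restitution <= 1.0:
            raise ValueError(f"restitution must lie in (0, 1], got {self.restitution}")
        if self.thermostat_rate < 0:
            raise ValueError("thermostat_rate must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class SimState:
    """Positions/velocities/diameters of all particles in a cubic periodic box."""

    positions: np.ndarray  # (n, 3), wrapped into [0, box_edge)
    velocities: np.ndarray  # (n, 3)
    diameters: np.ndarray  # (n,)
    masses: np.ndarray  # (n,)
    species_id: np.ndarray  # (n,) int
    box_edge: float
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def packing_fraction(self) -> float:
        return float((np.pi / 6.0 * self.diameters**3).sum() / self.box_edge**3)

    def kinetic_temperature(self) -> float:
        ke = 0.5 * (self.masses[:, None] * self.velocities**2).sum()
        return float(2.0 * ke / (3.0 * self.n))

    def total_momentum(self) -> np.ndarray:
        return (self.masses[:, None] * self.velocities).sum(axis=0)

    def kinetic_energy(self) -> float:
        return float(0.5 * (self.masses[:, None] * self.velocities**2).sum())

    def max_overlap(self) -> float:
        return float(K.max_overlap(self.positions, self.diameters, self.box_edge))

    def copy(self) -> "SimState":
        return SimState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            diameters=self.diameters.copy(),
            masses=self.masses.copy(),
            species_id=self.species_id.copy(),
            box_edge=self.box_edge,
            time=self.time,
        )


@dataclass
class EventRecord:
    """Recorded pair-collision stream (times non-decreasing)."""

    times: np.ndarray
    first: np.ndarray
    second: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Frames:
    """Sampled trajectory frames."""

    times: np.ndarray  # (nf,)
    positions: np.ndarray  # (nf, n, 3)
    velocities: np.ndarray  # (nf, n, 3)
    diameters: np.ndarray  # (nf, n) diameters at each sample time
    species_id: np.ndarray  # (n,)
    box_edge: float

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class RunResult:
    state: SimState
    events: EventRecord
    frames: Frames
    n_collisions: int
    virial_sum: float
    elapsed: float

    def compressibility_factor(self, temperature: Optional[float] = None) -> float:
        """Z = PV/(N k T) from the collisional virial over this run segment.

        Defaults to the final kinetic temperature, which is exact for
        elastic un-thermostatted segments (energy is conserved).
        """
        if self.elapsed <= 0:
            raise ValueError("no elapsed time in run segment")
        if temperature is None:
            temperature = self.state.kinetic_temperature()
        n = self.state.n
        return 1.0 + self.virial_sum / (3.0 * n * temperature * self.elapsed)


# ---------------------------------------------------------------------------
# spec-level single-event operations
# ---------------------------------------------------------------------------

def predict_pair_collision(r1, v1, d1, r2, v2, d2, box_edge) -> Optional[float]:
    """Earliest positive contact time of two ballistic spheres (None if never).

    Uses the minimum-image separation (the engine handles farther periodic
    images through cell crossings); raises on an already overlapping pair
    (corrupted state).
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    dr = r2 - r1
    dr -= box_edge * np.round(dr / box_edge)
    gap = np.linalg.norm(dr) - 0.5 * (d1 + d2)
    if gap < -1e-9:
        raise ValueError(f"input pair overlaps by {-gap:.3g}")
    dv = v2 - v1
    t = float(K._quad_contact_time(
        dr[0], dr[1], dr[2], dv[0], dv[1], dv[2], 0.5 * (d1 + d2), 0.0
    ))
    return None if not np.isfinite(t) else t


def resolve_collision(v1, v2, m1, m2, contact_normal, restitution: float = 1.0):
    """Post-collision velocities for a pair at contact.

    ``contact_normal`` points from particle 1 to particle 2.  The impulse
    acts along the normal; momentum is conserved exactly and the normal
    relative speed is scaled by ``-restitution``.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    nhat = np.asarray(contact_normal, dtype=float)
    nhat = nhat / np.linalg.norm(nhat)
    w = float((v2 - v1) @ nhat)
    if w >= 0:
        raise ValueError("pair is receding; no collision to resolve")
    mu = m1 * m2 / (m1 + m2)
    p = mu * (1.0 + restitution) * w
    return v1 + (p / m1) * nhat, v2 - (p / m2) * nhat


def thermostat_event(
    state: SimState, index: int, temperature: float, rng: np.random.Generator
) -> SimState:
    """Redraw one particle's velocity from the Maxwell-Boltzmann distribution.

    Mutates and returns ``state``; the particle's position is untouched.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    sd = np.sqrt(temperature / state.masses[index])
    state.velocities[index] = rng.normal(0.0, sd, size=3)
    return state


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------

def _box_edge_for(counts: np.ndarray, reduced_diameters: np.ndarray, phi: float) -> float:
    vol = float((counts * (np.pi / 6.0) * np.asarray(reduced_diameters) ** 3).sum())
    return (vol / phi) ** (1.0 / 3.0)


def initial_state(config: SimConfig, phi_init: Optional[float] = None) -> SimState:
    """Random non-overlapping configuration at the pre-compression density.

    The box edge is fixed by the *target* packing fraction with final
    (reduced) diameters; initial diameters are scaled down uniformly to
    ``phi_init`` (default ``min(0.15, target_phi)``), to be grown back by
    :func:`compress_to_phi`.  Velocities are Maxwell-Boltzmann at the
    configured temperature with zero total momentum.
    """
    ss = config.species_set
    if phi_init is None:
        phi_init = config.phi_init
    if phi_init is None:
        phi_init = min(0.15, config.target_phi)
    if phi_init > config.target_phi + 1e-12:
        raise ValueError("phi_init must not exceed target_phi")

    counts = realize_counts(ss.mole_fraction, config.n_particles)
    L = _box_edge_for(counts, ss.reduced_diameter, config.target_phi)

    species_id = np.repeat(np.arange(ss.n_species), counts)
    d_final = np.asarray(ss.reduced_diameter)[species_id].astype(float)
    masses = np.asarray(ss.reduced_mass)[species_id].astype(float)
    scale0 = (phi_init / config.target_phi) ** (1.0 / 3.0)
    diams = d_final * scale0

    # place largest species first (species are not guaranteed sorted by size)
    order = np.argsort(-diams, kind="stable")
    rng = np.random.default_rng(config.seed)
    place_seed = int(rng.integers(0, 2**31 - 1))
    phi0 = phi_init
    while True:
        pos_sorted, placed = K.rsi_place(diams[order], L, place_seed, 20000)
        if placed == config.n_particles:
            break
        phi0 *= 0.8
        if phi0 < 1e-4:
            raise RuntimeError("random insertion failed even at near-zero density")
        diams = d_final * (phi0 / config.target_phi) ** (1.0 / 3.0)
    pos = np.empty_like(pos_sorted)
    pos[order] = pos_sorted

    vel = rng.normal(0.0, 1.0, size=(config.n_particles, 3))
    vel *= np.sqrt(config.temperature / masses)[:, None]
    vel -= (masses[:, None] * vel).sum(axis=0) / masses.sum()

    return SimState(
        positions=pos,
        velocities=vel,
        diameters=diams,
        masses=masses,
        species_id=species_id,
        box_edge=L,
        time=0.0,
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

_STATUS_MSG = {
    K.TIME_REVERSED: "event time went backwards (engine bug)",
    K.HEAP_OVERFLOW: "event heap overflow",
}


def _drive(
    state: SimState,
    config: SimConfig,
    *,
    max_collisions: int = 0,
    t_max: float = np.inf,
    sample_times: Optional[np.ndarray] = None,
    growth: float = 0.0,
    t_growth_end: float = np.inf,
    record_events: int = 0,
    thermostat: bool = True,
    seed_offset: int = 0,
) -> RunResult:
    if max_collisions <= 0 and not np.isfinite(t_max) and (
        sample_times is None or len(sample_times) == 0
    ):
        raise ValueError("no termination condition given")
    n = state.n
    if sample_times is None:
        sample_times = np.empty(0, dtype=float)
    sample_times = np.asarray(sample_times, dtype=float)
    nf = len(sample_times)
    frames_pos = np.empty((nf, n, 3), dtype=float)
    frames_vel = np.empty((nf, n, 3), dtype=float)
    frames_scale = np.empty(nf, dtype=float)
    cap = int(record_events)
    rec_t = np.empty(max(cap, 1), dtype=float)
    rec_i = np.empty(max(cap, 1), dtype=np.int64)
    rec_j = np.empty(max(cap, 1), dtype=np.int64)

    tloc = np.full(n, state.time, dtype=float)
    nu = config.thermostat_rate if thermostat else 0.0
    t0 = state.time
    d_at_entry = state.diameters.copy()

    t_end, ncoll, virial, nsamp, nrec, status = K.evolve(
        state.positions, state.velocities, tloc, state.diameters, state.masses,
        float(state.box_edge),
        float(state.time), float(growth), float(t_growth_end),
        float(config.restitution), float(nu), float(config.temperature),
        int(max_collisions), float(t_max),
        sample_times, frames_pos, frames_vel, frames_scale,
        rec_t, rec_i, rec_j, cap,
        int((config.seed + 0x9E3779B1 * (seed_offset + 1)) % (2**31 - 1)),
    )
    state.time = float(t_end)

    if status in _STATUS_MSG:
        raise EngineError(_STATUS_MSG[status])
    if status == K.JAMMED:
        raise JammingError(state.packing_fraction(), config.target_phi)

    events = EventRecord(rec_t[:nrec].copy(), rec_i[:nrec].copy(), rec_j[:nrec].copy())
    frame_diams = d_at_entry[None, :] * frames_scale[:nsamp, None] if growth > 0 else (
        np.broadcast_to(state.diameters, (nsamp, n)).copy()
    )
    frames = Frames(
        times=sample_times[:nsamp].copy(),
        positions=frames_pos[:nsamp],
        velocities=frames_vel[:nsamp],
        diameters=frame_diams,
        species_id=state.species_id,
        box_edge=state.box_edge,
    )
    return RunResult(state, events, frames, int(ncoll), float(virial),
                     float(t_end - t0))


def compress_to_phi(state: SimState, config: SimConfig) -> SimState:
    """Grow diameters uniformly until the packing fraction reaches the target.

    Lubachevsky-Stillinger style: multiplicative growth at rate
    ``config.growth_rate`` preserves species diameter ratios.  On jamming
    the growth rate is halved and the compression retried once from the
    entry state; failure raises :class:`JammingError` with the achieved phi.
    """
    phi_now = state.packing_fraction()
    target = config.target_phi
    if phi_now >= target - 1e-4:
        return state
    rate = config.growth_rate
    if rate <= 0:
        raise ValueError("growth_rate must be positive to compress")
    backup = state.copy()
    for attempt in range(2):
        t_grow = ((target / phi_now) ** (1.0 / 3.0) - 1.0) / rate
        try:
            _drive(
                state, config,
                t_max=state.time + t_grow,
                growth=rate,
                t_growth_end=state.time + t_grow,
                thermostat=True,
                seed_offset=17 + attempt,
            )
            break
        except JammingError:
            if attempt == 1:
                raise
            rate *= 0.5
            state.positions[:] = backup.positions
            state.velocities[:] = backup.velocities
            state.diameters[:] = backup.diameters
            state.time = backup.time
    phi_end = state.packing_fraction()
    if abs(phi_end - target) > 1e-4:
        raise JammingError(phi_end, target)
    # growth does work on the system; reset the kinetic temperature before
    # equilibration (the thermostat then restores the Maxwellian shape)
    t_kin = state.kinetic_temperature()
    if t_kin > 0:
        state.velocities *= np.sqrt(config.temperature / t_kin)
    return state


def run(
    state: SimState,
    config: SimConfig,
    n_collisions: Optional[int] = None,
    duration: Optional[float] = None,
    sample_times: Optional[Sequence[float]] = None,
    record_events: int = 0,
    thermostat: bool = True,
    seed_offset: int = 0,
) -> RunResult:
    """Advance the state by a collision count and/or a time span.

    Frames are taken at the absolute ``sample_times``; pair collisions are
    recorded up to ``record_events`` entries.
    """
    t_max = np.inf if duration is None else state.time + float(duration)
    return _drive(
        state, config,
        max_collisions=0 if n_collisions is None else int(n_collisions),
        t_max=t_max,
        sample_times=None if sample_times is None else np.asarray(sample_times, float),
        record_events=record_events,
        thermostat=thermostat,
        seed_offset=seed_offset,
    )


def equilibrate(state: SimState, config: SimConfig) -> RunResult:
    """Run the configured number of collisions per particle (thermostatted)."""
    n_coll = config.equilibration_collisions_per_particle * state.n
    return run(state, config, n_collisions=n_coll, seed_offset=1)


def sample_frames(
    state: SimState,
    config: SimConfig,
    n_frames: int,
    collisions_per_particle_between: float = 2.0,
    collision_rate: Optional[float] = None,
    thermostat: bool = True,
) -> Frames:
    """Production sampling: ``n_frames`` frames spaced by a fixed number of
    collisions per particle (converted to time via the measured collision
    rate)."""
    if collision_rate is None:
        probe = run(state, config, n_collisions=5 * state.n, seed_offset=2)
        collision_rate = probe.n_collisions / probe.elapsed
    dt = collisions_per_particle_between * state.n / collision_rate
    times = state.time + dt * np.arange(1, n_frames + 1)
    res = run(
        state, config,
        duration=dt * (n_frames + 0.5),
        sample_times=times,
        thermostat=thermostat,
        seed_offset=3,
    )
    return res.frames


def simulate(
    config: SimConfig,
    n_frames: int = 50,
    collisions_per_particle_between: float = 2.0,
) -> tuple[SimState, Frames]:
    """Full pipeline: build, compress to target phi, equilibrate, sample."""
    state = initial_state(config)
    compress_to_phi(state, config)
    eq = equilibrate(state, config)
    frames = sample_frames(
        state, config, n_frames,
        collisions_per_particle_between=collisions_per_particle_between,
        collision_rate=eq.n_collisions / eq.elapsed if eq.elapsed > 0 else None,
    )
    return state, frames
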