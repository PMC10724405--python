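"""Seeded synthetic-data generators for every analysis stage.

All generators are deterministic given their parameters and seed; noise
is iid Gaussian on the measurement scale.  Presets carry published
midpoints/plateaus so demonstration datasets have realistic structure —
they are synthetic stand-ins, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assays import TurbidityCurve, boltzmann
from .engine.core import Frames
from .tensiometry import TensionTrace

__all__ = [
    "gen_turbidity",
    "gen_kinetics",
    "gen_tension",
    "gen_ideal_gas_frames",
    "TURBIDITY_PRESETS",
    "KINETICS_PRESET",
    "TENSION_FPS",
]

# half-solubility midpoints (crowder weight %) used as generator presets
TURBIDITY_PRESETS: dict[str, dict] = {
    "alpha": dict(a1=0.2, a2=1.6, x0=6.9, dx=0.8),
    "beta_h": dict(a1=0.2, a2=1.6, x0=9.6, dx=0.8),
    "beta_l": dict(a1=0.2, a2=1.6, x0=13.4, dx=0.8),
    "all_1mg": dict(a1=0.2, a2=1.6, x0=8.0, dx=0.8),
    "all_10mg": dict(a1=0.2, a2=2.4, x0=5.0, dx=0.8),
    "alpha:beta_h": dict(a1=0.2, a2=1.8, x0=7.9, dx=0.8),
    "alpha:beta_l": dict(a1=0.2, a2=1.7, x0=7.5, dx=0.8),
    "alpha:gamma": dict(a1=0.2, a2=1.6, x0=7.0, dx=0.8),
    "beta_h:beta_l": dict(a1=0.2, a2=1.6, x0=11.0, dx=0.8),
    "beta_h:gamma": dict(a1=0.2, a2=1.6, x0=12.5, dx=0.8),
}

# hydrogel turbidity kinetics: initial OD, plateau, half-max time (min)
KINETICS_PRESET = dict(od0=0.39, od_f=0.99, t_half=6.5, tau=1.5)

TENSION_FPS = 0.11  # pendant-drop imaging rate, samples per second


def gen_turbidity(
    a1: float,
    a2: float,
    x0: float,
    dx: float,
    x_grid: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    reentrant_decline: Optional[float] = None,
    reentrant_threshold: float = 15.0,
    seed: int = 0,
    condition: str = "synthetic",
) -> list[TurbidityCurve]:
    """Boltzmann-sigmoid turbidity curves with optional re-entrant decline.

    When ``reentrant_decline`` (a fraction, e.g. 0.286) is given, values
    above ``reentrant_threshold`` decay linearly so that the value at the
    grid maximum is reduced by that fraction relative to the threshold
    value.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    x = np.asarray(x_grid, dtype=float)
    y0 = boltzmann(x, a1, a2, x0, dx)
    if reentrant_decline is not None:
        hi = x > reentrant_threshold
        if hi.any():
            span = float(x.max() - reentrant_threshold)
            frac = (x[hi] - reentrant_threshold) / span
            y_at_thr = float(boltzmann(reentrant_threshold, a1, a2, x0, dx))
            y0 = y0.copy()
            y0[hi] = y_at_thr * (1.0 - reentrant_decline * frac)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        y = y0 + rng.normal(0.0, noise_sd, size=y0.shape) if noise_sd > 0 else y0.copy()
        out.append(TurbidityCurve(condition=f"{condition}", peg_percent=x, od=y))
    return out


def gen_kinetics(
    od0: float,
    od_f: float,
    t_half: float,
    tau: float,
    duration_min: float = 30.0,
    dt_min: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic turbidity-onset kinetics trace; returns (time_min, od)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.arange(0.0, duration_min + 0.5 * dt_min, dt_min)
    y = od0 + (od_f - od0) / (1.0 + np.exp(-(t - t_half) / tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return t, y


def gen_tension(
    gamma0: float,
    pi_final: float,
    rate_constant_s: float,
    duration_s: float = 2400.0,
    fps: float = TENSION_FPS,
    noise_sd: float = 0.0,
    n_drops: int = 1,
    seed: int = 0,
    condition: str = "synthetic",
) -> list[TensionTrace]:
    """Exponential-saturation tension decays, one trace per drop.

    gamma(t) = (gamma0 - pi_final) + pi_final * exp(-t / rate_constant_s),
    so the implied surface-pressure plateau is ``pi_final`` and the
    initial pressure rise rate is ``pi_final / rate_constant_s`` per second.
    """
    if rate_constant_s <= 0:
        raise ValueError("rate_constant_s must be positive")
    t = np.arange(0.0, duration_s, 1.0 / fps)
    base = (gamma0 - pi_final) + pi_final * np.exp(-t / rate_constant_s)
    rng = np.random.default_rng(seed)
    out = []
    for d in range(n_drops):
        g = base + rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else base.copy()
        if noise_sd > 0:
            g[0] = gamma0  # t0 defines the pressure origin exactly
        out.append(TensionTrace(condition=condition, drop_id=f"drop{d+1}",
                                time_s=t, gamma=g))
    return out


def gen_ideal_gas_frames(
    n_per_species: Sequence[int],
    box_edge: float,
    n_frames: int,
    seed: int = 0,
) -> Frames:
    """Uniform (Poisson, ideal-gas) point frames as a structure null model."""
    counts = np.asarray(n_per_species, dtype=int)
    if np.any(counts < 1):
        raise ValueError("counts must be >= 1")
    n = int(counts.sum())
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(n_frames, n, 3))
    species_id = np.repeat(np.arange(len(counts)), counts)
    return Frames(
        times=np.arange(n_frames, dtype=float),
        positions=pos,
        velocities=np.zeros_like(pos),
        diameters=np.zeros((n_frames, n)),
        species_id=species_id,
        box_edge=float(box_edge),
    )
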