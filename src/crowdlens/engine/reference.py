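"""Brute-force O(N^2) reference engine.

Synchronous, all-pairs event processing with 27-image collision
prediction.  Elastic, un-thermostatted, fixed diameters.  Used as an
independent oracle for the cell-list engine on small systems.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _kernels as K
from .core import EventRecord, SimState

__all__ = ["run_reference"]


@njit(cache=True)
def _earliest_pair(pos, vel, diams, L):
    n = pos.shape[0]
    best = np.inf
    bi = -1
    bj = -1
    for i in range(n):
        for j in range(i + 1, n):
            rn = 0.5 * (diams[i] + diams[j])
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    for oz in range(-1, 2):
                        tau = K._quad_contact_time(
                            pos[j, 0] - pos[i, 0] + ox * L,
                            pos[j, 1] - pos[i, 1] + oy * L,
                            pos[j, 2] - pos[i, 2] + oz * L,
                            vel[j, 0] - vel[i, 0],
                            vel[j, 1] - vel[i, 1],
                            vel[j, 2] - vel[i, 2],
                            rn, 0.0,
                        )
                        if tau < best:
                            best = tau
                            bi = i
                            bj = j
    return best, bi, bj


def run_reference(state: SimState, n_collisions: int) -> tuple[SimState, EventRecord]:
    """Process ``n_collisions`` elastic pair collisions; returns (state, events).

    The input state is mutated (synchronised to the final event time).
    """
    pos = state.positions
    vel = state.velocities
    diams = state.diameters
    masses = state.masses
    L = state.box_edge
    t = state.time

    vmax = float(np.linalg.norm(vel, axis=1).max()) if state.n else 0.0
    times, firsts, seconds = [], [], []

    while len(times) < n_collisions:
        tau, i, j = _earliest_pair(pos, vel, diams, L)
        if not np.isfinite(tau):
            break
        # bound the ballistic step so the 27-image prediction stays valid
        vmax = float(np.linalg.norm(vel, axis=1).max())
        horizon = 0.2 * L / vmax if vmax > 0 else np.inf
        step = min(tau, horizon)
        pos += vel * step
        pos %= L
        t += step
        if step < tau:
            continue  # refresh only

        dr = pos[j] - pos[i]
        dr -= L * np.round(dr / L)
        dist = np.linalg.norm(dr)
        nhat = dr / dist
        w = float((vel[j] - vel[i]) @ nhat)
        if w < 0:
            mu = masses[i] * masses[j] / (masses[i] + masses[j])
            p = 2.0 * mu * w
            vel[i] += p / masses[i] * nhat
            vel[j] -= p / masses[j] * nhat
            times.append(t)
            firsts.append(i)
            seconds.append(j)

    state.time = t
    return state, EventRecord(
        np.asarray(times), np.asarray(firsts, dtype=np.int64),
        np.asarray(seconds, dtype=np.int64),
    )
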