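"""Turbidity-curve sigmoid fitting and hydrogel kinetics metrics.

The crowding-agent turbidity curves are fitted with the Boltzmann sigmoid

    y(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx))

whose midpoint ``x0`` is the half-solubility point (the crowder weight
percentage at 50% of maximal scattering).  A fit only yields a
half-solubility when the upper plateau is actually reached inside the
measured range (the plateau-reliability rule); otherwise the value is
reported as undefined, mirroring the dash entries of solubility tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TurbidityCurve",
    "SigmoidFit",
    "KineticsMetrics",
    "boltzmann",
    "fit_boltzmann",
    "kinetics_metrics",
    "normalize_fluorescence",
    "delay_report",
    "FitError",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge after restarts."""


@dataclass
class TurbidityCurve:
    """One turbidity-vs-crowder curve (OD at fixed wavelength)."""

    condition: str
    peg_percent: np.ndarray
    od: np.ndarray
    replicate_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.peg_percent, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("peg_percent and od must be equal-length 1-D")
        if np.any(x < 0):
            raise ValueError("peg_percent must be non-negative")
        if np.any(np.diff(x) <= 0):
            raise ValueError("peg_percent must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("od must be finite")
        object.__setattr__(self, "peg_percent", x)
        object.__setattr__(self, "od", y)


@dataclass
class SigmoidFit:
    a1: float
    a2: float
    x0: float
    dx: float
    adj_r2: float
    plateau_reached: bool
    half_solubility: Optional[float]
    converged: bool = True


@dataclass
class KineticsMetrics:
    initial_od: float
    plateau_od: float
    percent_increase: float
    od_half: float
    t_half: Optional[float]


def boltzmann(x, a1, a2, x0, dx):
    """Boltzmann sigmoid: lower plateau a1, upper plateau a2, midpoint x0."""
    return a2 + (a1 - a2) / (1.0 + np.exp((np.asarray(x, dtype=float) - x0) / dx))


def fit_boltzmann(
    curve: TurbidityCurve,
    plateau_margin: float = 2.0,
    plateau_overshoot: float = 1.2,
    truncate_at_maximum: bool = True,
) -> SigmoidFit:
    """Nonlinear least-squares Boltzmann fit of a turbidity curve.

    The fit is restricted to the monotone regime by truncating at the
    curve maximum (re-entrant declines at extreme crowding are never
    fitted).  ``plateau_reached`` requires the midpoint plus
    ``plateau_margin * dx`` to lie within the data range and the fitted
    upper plateau not to overshoot the observed maximum by more than
    ``plateau_overshoot``; the half-solubility is ``x0`` only then.
    """
    x = curve.peg_percent
    y = curve.od
    if truncate_at_maximum:
        imax = int(np.argmax(y))
        # cut only a genuine re-entrant decline (trailing OD well below the
        # maximum); truncating at a noise maximum would bias the upper plateau
        if imax >= 4 and y[-1] < 0.9 * y[imax]:
            x = x[: imax + 1]
            y = y[: imax + 1]
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit")
    y_range = float(y.max() - y.min())
    if y_range <= 0:
        return SigmoidFit(float(y.mean()), float(y.mean()), math.nan, math.nan,
                          0.0, False, None, converged=False)

    # initial guesses: plateaus at extremes, midpoint at half-range crossing
    a1_0 = float(y.min())
    a2_0 = float(y.max())
    half = 0.5 * (a1_0 + a2_0)
    above = np.nonzero(y >= half)[0]
    x0_0 = float(x[above[0]]) if len(above) else float(x[len(x) // 2])
    dx_0 = float((x.max() - x.min()) / 10.0)

    # physically motivated box: plateaus near the observed OD extremes,
    # midpoint near the sampled range, width below a third of the range
    # (a wider sigmoid is unidentifiable on the design anyway)
    span = float(x.max() - x.min())
    lower = [a1_0 - 0.25 * y_range, a1_0 - 0.25 * y_range,
             float(x.min()) - 0.25 * span, 1e-6]
    upper = [a2_0 + 0.25 * y_range, a2_0 + 0.25 * y_range,
             float(x.max()) + 0.25 * span, span / 3.0]
    popt = None
    for scale in (1.0, 0.5, 2.0, 0.25):
        try:
            popt, _ = curve_fit(
                boltzmann, x, y,
                p0=[a1_0, a2_0, x0_0, dx_0 * scale],
                bounds=(lower, upper),
                maxfev=20000,
            )
            break
        except RuntimeError:
            continue
    if popt is None:
        raise FitError(f"Boltzmann fit did not converge for {curve.condition!r}")
    a1, a2, x0, dx = (float(v) for v in popt)

    resid = y - boltzmann(x, a1, a2, x0, dx)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = len(x), 4
    if ss_tot > 0 and n > p + 1:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        adj_r2 = math.nan

    plateau_reached = bool(
        (x0 + plateau_margin * dx <= float(x.max()))
        and (a2 <= plateau_overshoot * float(y.max()))
        and (a2 - a1 > 0)
    )
    return SigmoidFit(
        a1=a1, a2=a2, x0=x0, dx=dx, adj_r2=adj_r2,
        plateau_reached=plateau_reached,
        half_solubility=x0 if plateau_reached else None,
    )


def kinetics_metrics(
    time_min: Sequence[float],
    od: Sequence[float],
    baseline_samples: int = 3,
    plateau_fraction: float = 0.1,
) -> KineticsMetrics:
    """Initial/plateau OD, percent increase, and half-max crossing time.

    ``initial_od`` averages the leading ``baseline_samples`` samples;
    ``plateau_od`` the trailing ``plateau_fraction`` of the trace.
    ``od_half`` is their midpoint and ``t_half`` the linearly interpolated
    first crossing (None if never crossed).
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and od must be equal-length 1-D")
    if len(t) < 10:
        raise ValueError("need at least 10 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    initial = float(y[:baseline_samples].mean())
    n_tail = max(1, int(round(plateau_fraction * len(y))))
    plateau = float(y[-n_tail:].mean())
    od_half = 0.5 * (initial + plateau)
    percent = 100.0 * (plateau - initial) / initial if initial != 0 else math.inf

    if abs(plateau - initial) <= 1e-12 * max(1.0, abs(initial)):
        t_half = None  # no rise: half-max crossing undefined
    else:
        t_half = _first_crossing(t, y, od_half)
    return KineticsMetrics(
        initial_od=initial, plateau_od=plateau, percent_increase=percent,
        od_half=od_half, t_half=t_half,
    )


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    if y[0] >= level:
        return float(t[0])
    above = np.nonzero(y >= level)[0]
    if len(above) == 0:
        return None
    k = int(above[0])
    t0, t1 = t[k - 1], t[k]
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def normalize_fluorescence(
    trace: Sequence[float], reference_trace: Optional[Sequence[float]] = None
) -> np.ndarray:
    """(t - MIN) / (MAX - MIN) normalisation of a fluorescence trace.

    MIN is always the trace's own minimum.  When a ``reference_trace`` is
    supplied (the low-signal-control rule), MAX is taken from the
    reference instead of the trace itself.
    """
    y = np.asarray(trace, dtype=float)
    lo = float(y.min())
    hi = float(np.asarray(reference_trace, dtype=float).max()) if reference_trace is not None else float(y.max())
    if hi <= lo:
        raise ValueError("zero dynamic range: MAX must exceed MIN")
    return (y - lo) / (hi - lo)


def delay_report(
    control: KineticsMetrics,
    treated_time_min: Sequence[float],
    treated_od: Sequence[float],
) -> Optional[float]:
    """Time for a treated trace to reach the control's half-max OD.

    Returns the interpolated first-crossing time, or None (flagged) if the
    treated trace never reaches the control's ``od_half``.
    """
    if control.t_half is None:
        raise ValueError("control trace has no defined half-max crossing")
    t = np.asarray(treated_time_min, dtype=float)
    y = np.asarray(treated_od, dtype=float)
    return _first_crossing(t, y, control.od_half)
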