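"""Surface-pressure statistics and pairwise interaction classification.

Surface tension traces gamma(t) are converted to surface pressure
Pi(t) = gamma(t0) - gamma(t).  Per condition, the initial adsorption rate
is the mean pointwise slope over the first 100 s and the final pressure
is the mean over the trailing 240 s.  Conditions are compared with a
one-way ANOVA followed by Bonferroni-corrected homoscedastic two-tailed
t-tests; a mixture is called *repulsive* against a control when either
metric is significantly higher, and *attractive* only when both are
significantly lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TensionTrace",
    "PressureStats",
    "InteractionCall",
    "to_surface_pressure",
    "initial_rate",
    "final_pressure",
    "anova_posthoc",
    "AnovaResult",
    "classify_interaction",
    "condition_stats",
]

RATE_WINDOW_S = 100.0
FINAL_WINDOW_S = 240.0


@dataclass
class TensionTrace:
    """One pendant-drop surface tension time series (mN/m vs seconds)."""

    condition: str
    drop_id: str
    time_s: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        if t.ndim != 1 or t.shape != g.shape:
            raise ValueError("time_s and gamma must be equal-length 1-D")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "gamma", g)


@dataclass
class PressureStats:
    condition: str
    initial_rate: float  # mN/m/min
    initial_rate_se: float
    final_pressure: float  # mN/m
    final_pressure_se: float
    n_rate_points: int
    n_final_points: int
    rate_points: np.ndarray = field(repr=False, default=None)
    final_points: np.ndarray = field(repr=False, default=None)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairs: list  # (label_a, label_b)
    p_raw: np.ndarray
    p_corrected: np.ndarray
    alpha: float

    def p_for(self, a: str, b: str) -> float:
        for k, (x, y) in enumerate(self.pairs):
            if {x, y} == {a, b}:
                return float(self.p_corrected[k])
        raise KeyError(f"no comparison between {a!r} and {b!r}")


@dataclass
class InteractionCall:
    mixture: str
    control: str
    rate_significant: bool
    rate_direction: int  # +1 higher than control, -1 lower, 0 n.s.
    final_significant: bool
    final_direction: int
    label: str  # {"repulsive", "attractive", "none"}


def to_surface_pressure(trace: TensionTrace) -> np.ndarray:
    """Pi(t) = gamma(t0) - gamma(t); Pi(t0) = 0 by construction."""
    if len(trace.time_s) < 2:
        raise ValueError("need at least 2 samples")
    return trace.gamma[0] - trace.gamma


def initial_rate(
    time_s: np.ndarray, pressure: np.ndarray, window_s: float = RATE_WINDOW_S
) -> np.ndarray:
    """Pointwise slopes (mN/m/min) over the leading linear window.

    Central finite differences at interior samples, one-sided at the
    ends, restricted to t <= window_s.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(pressure, dtype=float)
    mask = t <= window_s
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 samples within the first {window_s} s")
    t = t[mask]
    y = y[mask]
    slopes = np.gradient(y, t)  # central interior, one-sided ends
    return slopes * 60.0


def final_pressure(
    time_s: np.ndarray, pressure: np.ndarray, window_s: float = FINAL_WINDOW_S
) -> np.ndarray:
    """Samples of Pi within the trailing ``window_s`` of the trace."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(pressure, dtype=float)
    duration = float(t[-1] - t[0])
    if duration < window_s:
        raise ValueError(f"trace spans {duration:.0f} s < final window {window_s:.0f} s")
    return y[t >= t[-1] - window_s]


def condition_stats(traces: Sequence[TensionTrace]) -> PressureStats:
    """Pool per-point rate and final-pressure samples across drops of one condition."""
    if not traces:
        raise ValueError("no traces given")
    cond = traces[0].condition
    rates = []
    finals = []
    for tr in traces:
        if tr.condition != cond:
            raise ValueError("mixed conditions in condition_stats")
        pi = to_surface_pressure(tr)
        rates.append(initial_rate(tr.time_s, pi))
        finals.append(final_pressure(tr.time_s, pi))
    rates = np.concatenate(rates)
    finals = np.concatenate(finals)
    return PressureStats(
        condition=cond,
        initial_rate=float(rates.mean()),
        initial_rate_se=float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0,
        final_pressure=float(finals.mean()),
        final_pressure_se=float(finals.std(ddof=1) / np.sqrt(len(finals))) if len(finals) > 1 else 0.0,
        n_rate_points=len(rates),
        n_final_points=len(finals),
        rate_points=rates,
        final_points=finals,
    )


def anova_posthoc(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA plus all-pairs Bonferroni-corrected pooled-variance t-tests."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {k!r} needs at least 2 points")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group; F undefined")

    f_stat, p_val = stats.f_oneway(*arrays)

    pairs = []
    p_raw = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            _, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
            pairs.append((labels[i], labels[j]))
            p_raw.append(float(p))
    p_raw = np.asarray(p_raw)
    p_corr = np.minimum(1.0, p_raw * len(pairs))
    return AnovaResult(
        f_statistic=float(f_stat), p_value=float(p_val),
        pairs=pairs, p_raw=p_raw, p_corrected=p_corr, alpha=alpha,
    )


def classify_interaction(
    mix_stats: PressureStats,
    ctrl_stats: PressureStats,
    rate_p: float,
    final_p: float,
    alpha: float = 0.05,
) -> InteractionCall:
    """Label a mixture/control pairing from its significance pattern.

    Repulsive when either the final pressure OR the initial rate is
    significantly greater than the control; attractive only when BOTH are
    significantly lower; otherwise no call.
    """
    rate_sig = rate_p < alpha
    final_sig = final_p < alpha
    rate_dir = int(np.sign(mix_stats.initial_rate - ctrl_stats.initial_rate)) if rate_sig else 0
    final_dir = int(np.sign(mix_stats.final_pressure - ctrl_stats.final_pressure)) if final_sig else 0

    if (final_sig and final_dir > 0) or (rate_sig and rate_dir > 0):
        label = "repulsive"
    elif final_sig and final_dir < 0 and rate_sig and rate_dir < 0:
        label = "attractive"
    else:
        label = "none"
    return InteractionCall(
        mixture=mix_stats.condition, control=ctrl_stats.condition,
        rate_significant=rate_sig, rate_direction=rate_dir,
        final_significant=final_sig, final_direction=final_dir,
        label=label,
    )
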