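"""Outcome classification and trace statistics shared by both simulators.

A run of either scale produces a :class:`RunResult`: aligned time
series of population summaries, an optional point trace and snapshots,
and a terminal outcome label (``"Alive"`` when both species persist to
the time limit, ``"Extinction"`` otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError

__all__ = ["RunResult", "WaveCondition", "TraceStats", "classify_outcome",
           "trace_statistics", "wave_condition"]


@dataclass
class RunResult:
    """Time series and terminal label of one simulation run.

    ``replicase_series`` / ``parasite_series`` are mean densities for
    the lattice model and agent counts for the agent model;
    ``resource_series`` exists only for the lattice model.
    ``affinity_series`` is the population-mean parasite affinity
    (density-weighted mean a, or mean kP).
    """

    times: np.ndarray
    replicase_series: np.ndarray
    parasite_series: np.ndarray
    affinity_series: np.ndarray
    resource_series: np.ndarray | None = None
    trace: np.ndarray | None = None
    affinity_min_series: np.ndarray | None = None
    affinity_max_series: np.ndarray | None = None
    steps: np.ndarray | None = None
    snapshots: Any = None
    final_state: Any = None
    outcome: str | None = None

    def __post_init__(self):
        ln = len(self.times)
        for name in ("replicase_series", "parasite_series",
                     "affinity_series"):
            if len(getattr(self, name)) != ln:
                raise ParameterError("series must share one length")


@dataclass(frozen=True)
class WaveCondition:
    """Measured ingredients of the wave-persistence condition.

    v is the wavefront expansion velocity, T the period of the local
    growth/decay cycle, and P_area the minimal area a population must
    cover to be able to regrow after almost dying out.  All three are
    measured (or user-supplied) quantities; the model does not predict
    them.
    """

    v: float
    T: float
    P_area: float

    def __post_init__(self):
        if self.v < 0 or self.T < 0 or self.P_area < 0:
            raise ParameterError("v, T, P_area must be >= 0")


@dataclass(frozen=True)
class TraceStats:
    min: float
    max: float
    mean: float
    period: float | None
    period_defined: bool


def classify_outcome(result: RunResult, eps: float = 1e-6) -> str:
    """``"Extinction"`` if either species' final value is below eps.

    For agent counts an eps below 1 (e.g. 0.5) makes the test "count is
    zero".  The label is invariant to rescaling the series as long as
    the final values stay above eps.
    """
    if len(result.times) == 0:
        raise ParameterError("empty run result")
    r_last = result.replicase_series[-1]
    p_last = result.parasite_series[-1]
    return "Extinction" if (r_last < eps or p_last < eps) else "Alive"


def trace_statistics(trace, burn_in: float = 0.5, dt: float = 1.0,
                     prominence: float = 0.05) -> TraceStats:
    """Extrema, mean and an autocorrelation period of a point trace.

    The first ``burn_in`` fraction of the trace is discarded (the
    initial transient away from the uniform start must not contaminate
    the oscillation band).  The period is estimated as the mean spacing
    of peaks of the normalized autocorrelation, in units of ``dt`` per
    sample; if no secondary peak exceeds ``prominence`` the period is
    flagged undefined.
    """
    trace = np.asarray(trace, dtype=float)
    if not 0.0 <= burn_in < 1.0:
        raise ParameterError("burn_in must lie in [0, 1)")
    start = int(len(trace) * burn_in)
    x = trace[start:]
    if len(x) < 2:
        raise ParameterError("trace too short after burn-in")
    mn, mx, mean = float(x.min()), float(x.max()), float(x.mean())
    if mx == mn:
        return TraceStats(mn, mx, mean, None, False)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[len(xc) - 1:]
    acf = acf / acf[0]
    peaks, _ = find_peaks(acf, prominence=prominence)
    if len(peaks) == 0:
        return TraceStats(mn, mx, mean, None, False)
    spacings = np.diff(peaks, prepend=0)
    period = float(np.mean(spacings)) * dt
    return TraceStats(mn, mx, mean, period, True)


def wave_condition(wc: WaveCondition) -> bool:
    """Persistence-by-waves condition: pi*(v*T)**2 >= P_area.

    A regrowth nucleus travelling at front speed v for one cycle T
    covers a disc of area pi*(v*T)**2; waves can sustain the system iff
    that disc is at least the minimal regrowth area.
    """
    if not (math.isfinite(wc.v) and math.isfinite(wc.T)
            and math.isfinite(wc.P_area)):
        raise ParameterError("wave condition fields must be finite")
    return math.pi * (wc.v * wc.T) ** 2 >= wc.P_area
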