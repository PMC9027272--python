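"""Closed-form well-mixed analysis of the replicase-parasite system.

In a spatially homogeneous ("well-mixed") state the Laplacians vanish
and the density model reduces to three coupled ODEs for resource n,
replicase r and parasite p:

    dn/dt = n0 - n*r*(aR*r + aP*p)
    dr/dt = (1-m)*aR*n*r**2 - dR*r
    dp/dt = m*aR*n*r**2 + aP*n*r*p - dP*p

This module provides the interior equilibrium of that system, the
persistence inequality that decides whether it exists, the linearized
self-amplification rate of replicase perturbations, and the pendulum
reduction: substituting y = 1/r (and eliminating n) turns the
replicase-resource subsystem with p held fixed into

    y'' = P(y) + Q(y) * y'
    P(y) = dR*aP*p - n0*(1-m)*aR + dR*aR/y
    Q(y) = dR - aP*p/y - aR/y**2

which reads as a pendulum: P is a position-dependent force with a
single root yE, and Q is a friction coefficient that is non-positive
for y <= yC and positive (energy-pumping) beyond the critical point yC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import _kernels
from .errors import (
    DegenerateCoexistenceError,
    IneffectiveReplicationError,
    NoSteadyStateError,
    ParameterError,
)
from .params import PDEParams

__all__ = [
    "SteadyState",
    "PendulumReduction",
    "PendulumTrajectory",
    "WellMixedTrajectory",
    "persistence_margin",
    "steady_state",
    "steady_state_residuals",
    "linear_growth_rate",
    "pendulum_coefficients",
    "integrate_pendulum",
    "integrate_well_mixed",
]


@dataclass(frozen=True)
class SteadyState:
    """Interior well-mixed equilibrium (r, p, n) and the ratio A = p/r."""

    r: float
    p: float
    n: float
    A: float


@dataclass(frozen=True)
class PendulumReduction:
    """Coefficients of the y = 1/r pendulum equation at fixed parasite density.

    Attributes
    ----------
    yE : float
        Equilibrium inverse replicase density (root of the force P).
    yC : float
        Critical inverse density: largest y at which the friction Q is
        still non-positive.  Beyond yC friction pumps energy in and the
        replicase population can collapse (y -> infinity).
    p_fixed : float
        Parasite density treated as a constant parameter.
    P, Q : callable
        The force and friction terms, vectorized over y.
    """

    yE: float
    yC: float
    p_fixed: float
    P: Callable[[np.ndarray], np.ndarray]
    Q: Callable[[np.ndarray], np.ndarray]
    # raw coefficients of the Eq-grouping P(y) = c0 + dR*aR/y,
    # Q(y) = dR - aP*p/y - aR/y**2 (kept for the compiled integrator)
    c0: float = 0.0
    dR: float = 0.0
    aR: float = 0.0
    aPp: float = 0.0


@dataclass(frozen=True)
class PendulumTrajectory:
    t: np.ndarray
    y: np.ndarray
    v: np.ndarray
    diverged: bool


@dataclass(frozen=True)
class WellMixedTrajectory:
    t: np.ndarray
    n: np.ndarray
    r: np.ndarray
    p: np.ndarray


def persistence_margin(params: PDEParams, aP: float | None = None) -> float:
    """Signed margin of the persistence inequality 1 - m > aP*dR/(aR*dP).

    Returns ``(1 - m) - aP*dR/(aR*dP)``.  A positive value means the
    inequality holds and a positive well-mixed steady state exists; at
    zero the system sits exactly on the persistence boundary.
    """
    if aP is None:
        aP = params.aP0
    if params.dP <= 0:
        raise ParameterError("persistence margin requires dP > 0")
    if params.aR <= 0:
        raise ParameterError("persistence margin requires aR > 0")
    return (1.0 - params.m) - aP * params.dR / (params.aR * params.dP)


def steady_state(params: PDEParams, aP: float | None = None) -> SteadyState:
    """Closed-form interior equilibrium of the well-mixed system.

    With 0 < m < 1 and a positive persistence margin:

        A = m*aR*dR / (dP*(1-m)*aR - aP*dR)
        n = dR**2 * (aR + aP*A) / (n0 * ((1-m)*aR)**2)
        r = dR / ((1-m)*aR*n)
        p = A*r

    Raises
    ------
    IneffectiveReplicationError
        If m = 1 (replication never reproduces a replicase).
    DegenerateCoexistenceError
        If m = 0: with aR*dP == aP*dR any proportion p/r is an
        equilibrium; otherwise no mixed equilibrium exists.
    NoSteadyStateError
        If the denominator dP*(1-m)*aR - aP*dR is not positive (the
        persistence inequality fails).
    """
    if aP is None:
        aP = params.aP0
    aR, dR, dP, m, n0 = params.aR, params.dR, params.dP, params.m, params.n0
    if m >= 1.0:
        raise IneffectiveReplicationError(
            "m = 1: replicase copies are all parasites")
    if m == 0.0:
        raise DegenerateCoexistenceError(aR * dP == aP * dR)
    denom = dP * (1.0 - m) * aR - aP * dR
    if denom <= 0.0:
        raise NoSteadyStateError(
            "persistence inequality violated: no positive steady state")
    A = m * aR * dR / denom
    n = dR * dR * (aR + aP * A) / (n0 * ((1.0 - m) * aR) ** 2)
    r = dR / ((1.0 - m) * aR * n)
    p = A * r
    return SteadyState(r=r, p=p, n=n, A=A)


def steady_state_residuals(
    params: PDEParams, state: SteadyState, aP: float | None = None
) -> tuple[float, float, float]:
    """Relative residuals of the three balance equations at ``state``.

    The raw residuals are the right-hand sides of the well-mixed
    system; each is scaled by the magnitude of its largest constituent
    term so that "zero to numerical precision" is scale-free.
    """
    if aP is None:
        aP = params.aP0
    aR, dR, dP, m, n0 = params.aR, params.dR, params.dP, params.m, params.n0
    n, r, p = state.n, state.r, state.p
    f_n = n0 - n * r * (aR * r + aP * p)
    f_r = (1.0 - m) * aR * n * r * r - dR * r
    f_p = m * aR * n * r * r + aP * n * r * p - dP * p
    s_n = max(abs(n0), abs(n * r * (aR * r + aP * p)))
    s_r = max(abs((1.0 - m) * aR * n * r * r), abs(dR * r))
    s_p = max(abs(m * aR * n * r * r) + abs(aP * n * r * p), abs(dP * p))
    return (f_n / s_n if s_n else f_n,
            f_r / s_r if s_r else f_r,
            f_p / s_p if s_p else f_p)


def linear_growth_rate(params: PDEParams, n: float, r: float) -> float:
    """Linearized self-amplification rate of replicase perturbations.

    At an interior equilibrium the derivative of dr/dt with respect to
    r collapses to (1-m)*aR*n*r, which is strictly positive whenever
    m < 1 and aR, n, r > 0: any replicase perturbation is locally
    magnified, so linearization alone cannot establish stability.
    """
    if n < 0 or r < 0:
        raise ParameterError("densities must be >= 0")
    return (1.0 - params.m) * params.aR * n * r


def pendulum_coefficients(
    params: PDEParams, aP: float | None = None, p_fixed: float = 0.0
) -> PendulumReduction:
    """Build the pendulum reduction y'' = P(y) + Q(y) y' at fixed p.

    Raises
    ------
    NoSteadyStateError
        If p_fixed >= n0*(1-m)*aR/(dR*aP): the force P then has no
        positive root (yE would be non-positive).
    """
    if aP is None:
        aP = params.aP0
    aR, dR, m, n0 = params.aR, params.dR, params.m, params.n0
    if dR <= 0:
        raise ParameterError("pendulum reduction requires dR > 0")
    if p_fixed < 0:
        raise ParameterError("p_fixed must be >= 0")
    denom = n0 * (1.0 - m) * aR - dR * aP * p_fixed
    if denom <= 0.0:
        raise NoSteadyStateError(
            "p_fixed too large: force term has no positive equilibrium")
    yE = dR * aR / denom
    app = aP * p_fixed
    yC = (app + math.sqrt(app * app + 4.0 * aR * dR)) / (2.0 * dR)

    def P(y):
        y = np.asarray(y, dtype=float)
        return dR * app - n0 * (1.0 - m) * aR + dR * aR / y

    def Q(y):
        y = np.asarray(y, dtype=float)
        return dR - app / y - aR / (y * y)

    return PendulumReduction(yE=yE, yC=yC, p_fixed=p_fixed, P=P, Q=Q,
                             c0=dR * app - n0 * (1.0 - m) * aR,
                             dR=dR, aR=aR, aPp=app)


def integrate_pendulum(
    red: PendulumReduction,
    y0: float,
    v0: float = 0.0,
    horizon: float = 1000.0,
    dt: float = 0.1,
    divergence_factor: float = 1e6,
) -> PendulumTrajectory:
    """Integrate y'' = P(y) + Q(y) y' with fixed-step RK4.

    The trajectory is truncated with ``diverged=True`` as soon as y
    exceeds ``divergence_factor * yE`` (the collapse regime has no
    finite limit) or y falls to 0 or below (the reduction leaves its
    domain; 1/r cannot vanish).
    """
    if y0 <= 0:
        raise ParameterError("y0 must be > 0 (y is an inverse density)")
    n_steps = int(round(horizon / dt))
    t = np.arange(n_steps + 1) * dt
    ys = np.empty(n_steps + 1)
    vs = np.empty(n_steps + 1)
    ys[0], vs[0] = y0, v0
    cap = divergence_factor * red.yE
    if n_steps == 0:
        return PendulumTrajectory(t=t, y=ys, v=vs, diverged=False)
    last, diverged = _kernels.pendulum_kernel(
        t, ys, vs, red.c0, red.dR * red.aR, red.dR, red.aPp, red.aR,
        dt, cap)
    end = last + 1
    return PendulumTrajectory(t=t[:end], y=ys[:end], v=vs[:end],
                              diverged=bool(diverged))


def integrate_well_mixed(
    params: PDEParams,
    aP: float | None = None,
    init: tuple[float, float, float] = (1.0, 1.0, 1.0),
    horizon: float = 1000.0,
    dt: float | None = None,
    clamp_p: bool = False,
) -> WellMixedTrajectory:
    """Integrate the spatially homogeneous (n, r, p) system with RK4.

    Parameters
    ----------
    init : tuple
        Initial (n, r, p), all >= 0.
    clamp_p : bool
        Hold p constant at its initial value (the regime in which the
        pendulum reduction is exact).  The approximation of treating p
        as a parameter is only trustworthy when p in fact changes
        slowly; this flag makes the assumption explicit rather than
        guessing a validity bound.

    Negative densities produced by a step are clamped to 0; extinction
    is a valid outcome, not an error.
    """
    if aP is None:
        aP = params.aP0
    if dt is None:
        dt = params.dt
    n_init, r_init, p_init = init
    if min(init) < 0:
        raise ParameterError("initial densities must be >= 0")
    n_steps = int(round(horizon / dt))
    out = np.empty((n_steps + 1, 3))
    out[0] = (n_init, r_init, p_init)
    if n_steps:
        _kernels.well_mixed_kernel(out, params.aR, aP, params.dR, params.dP,
                                   params.m, params.n0, dt, clamp_p)
    t = np.arange(n_steps + 1) * dt
    return WellMixedTrajectory(t=t, n=out[:, 0], r=out[:, 1], p=out[:, 2])
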