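"""Discretized 2D reaction-diffusion simulator of the RP model.

The lattice scheme is forward Euler with a neighbour-average diffusion
stencil on a torus (8-cell Moore ring by default, 4-cell von Neumann
optional); the lattice spacing is 1, so diffusion constants absorb the
spacing.  Each cell carries four variables: the
replicase density r, the parasite density p, the local mean parasite
affinity a, and the resource density n.  Per cell and per step:

    new_replicases = aR*dt*r^2*(1-m)*n
    new_parasites  = dt*r*(aR*r*m + a*p)*n

and if their sum exceeds the locally available resource n both are
rescaled by n/sum (resource limitation).  r, p and n are then updated
with growth, decay, production and diffusion; the affinity diffuses as
the conserved mass a*p (affinity is carried by parasites, it cannot
diffuse by itself) and the local mean is recovered by dividing the
transported mass by the equally transported parasite density.  Finally
the
affinity receives a Gaussian mutation kick with standard deviation
sigma_a*sqrt(dt)/sqrt(p): large local populations evolve slowly.
Negative densities are clamped to 0 and a to [a_min, a_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import NumericalInstabilityError, ParameterError
from .metrics import RunResult, classify_outcome
from .params import PDEParams, PDERunConfig

__all__ = ["GridState", "init_uniform", "neighbor_average", "pde_step",
           "run_pde"]

#: density floor inside sqrt(p) of the mutation term (empty cells)
P_FLOOR = 1e-12


@dataclass
class GridState:
    """Four co-located 2D lattices plus elapsed time."""

    r: np.ndarray
    p: np.ndarray
    a: np.ndarray
    n: np.ndarray
    t: float = 0.0
    step: int = 0

    def validate(self, a_min: float = 0.0, a_max: float = 1.0) -> None:
        shape = self.r.shape
        for name in ("p", "a", "n"):
            if getattr(self, name).shape != shape:
                raise ParameterError("all four lattices must share a shape")
        for name in ("r", "p", "a", "n"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise NumericalInstabilityError(f"non-finite values in {name}")
        if (self.r < 0).any() or (self.p < 0).any() or (self.n < 0).any():
            raise ParameterError("densities must be >= 0")
        if (self.a < a_min).any() or (self.a > a_max).any():
            raise ParameterError("a outside [a_min, a_max]")

    def copy(self) -> "GridState":
        return GridState(self.r.copy(), self.p.copy(), self.a.copy(),
                         self.n.copy(), self.t, self.step)


def init_uniform(config: PDERunConfig) -> GridState:
    """All four fields constant at 1.0 (a at the configured aP0), t = 0."""
    shape = (config.sizeX, config.sizeY)
    return GridState(
        r=np.ones(shape), p=np.ones(shape),
        a=np.full(shape, config.params.aP0), n=np.ones(shape),
    )


def neighbor_average(field: np.ndarray, boundary: str = "periodic",
                     neighborhood: str = "moore") -> np.ndarray:
    """Mean of a cell's adjacent neighbours, with periodic wrap.

    ``neighborhood`` selects the 8-cell Moore ring (default) or the
    4-cell von Neumann cross.  The Moore average keeps the explicit
    diffusion update ``f + D*dt*(avg - f)`` stable up to D*dt = 1: the
    alternating (checkerboard) mode averages to zero over the 8-ring,
    whereas over the 4-cross it is marginal exactly at D*dt = 1 — the
    resource diffusion constant of the default parameter set.

    On a 1x1 lattice every cell is its own wrapped neighbour, so the
    average equals the field itself (diffusion vanishes).
    """
    if boundary != "periodic":
        raise ParameterError("only periodic boundaries are implemented")
    f = np.asarray(field, dtype=float)
    four = (np.roll(f, 1, 0) + np.roll(f, -1, 0)
            + np.roll(f, 1, 1) + np.roll(f, -1, 1))
    if neighborhood == "von_neumann":
        return four * 0.25
    if neighborhood != "moore":
        raise ParameterError("neighborhood must be moore or von_neumann")
    up = np.roll(f, 1, 0)
    dn = np.roll(f, -1, 0)
    return (four + np.roll(up, 1, 1) + np.roll(up, -1, 1)
            + np.roll(dn, 1, 1) + np.roll(dn, -1, 1)) * 0.125


def _step_numpy(r, p, a, n, normals, par: PDEParams,
                neighborhood: str = "moore"):
    """Vectorized reference implementation of one lattice step."""
    c_rep = par.aR * par.dt
    one_m = 1.0 - par.m
    new_r = c_rep * r * r * one_m * n
    new_p = par.dt * r * (par.aR * r * par.m + a * p) * n
    used = new_r + new_p
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(used > n, n / used, 1.0)
    new_r = new_r * scale
    new_p = new_p * scale
    avg_r = neighbor_average(r, neighborhood=neighborhood)
    avg_p = neighbor_average(p, neighborhood=neighborhood)
    avg_n = neighbor_average(n, neighborhood=neighborhood)
    ap = a * p
    avg_ap = neighbor_average(ap, neighborhood=neighborhood)
    r2 = r + new_r - (par.dR * par.dt) * r + (par.D * par.dt) * (avg_r - r)
    p2 = p + new_p - (par.dP * par.dt) * p + (par.D * par.dt) * (avg_p - p)
    new_ap = ap + (par.D * par.dt) * (avg_ap - ap)
    # mean affinity = transported mass / transported carrier density;
    # growth and decay copy or remove parasites without changing the
    # local mean, so only the diffusion operator enters here
    p_diff = p + (par.D * par.dt) * (avg_p - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        a2 = np.where(p_diff > 0.0, new_ap / p_diff, a)
    n2 = (n + par.n0 * par.dt - new_r - new_p
          + (par.Dn * par.dt) * (avg_n - n))
    if normals is not None:
        s0 = par.sigma_a * np.sqrt(par.dt)
        a2 = a2 + (s0 / np.sqrt(np.maximum(p, P_FLOOR))) * normals
    np.maximum(r2, 0.0, out=r2)
    np.maximum(p2, 0.0, out=p2)
    np.maximum(n2, 0.0, out=n2)
    np.clip(a2, par.a_min, par.a_max, out=a2)
    return r2, p2, a2, n2


def pde_step(state: GridState, config: PDERunConfig,
             rng: np.random.Generator | None = None) -> GridState:
    """Advance the lattice by one time step (NumPy reference path).

    The mutation kick uses ``rng``; with ``sigma_a == 0`` (or no rng)
    the step is fully deterministic.
    """
    par = config.params
    normals = None
    if par.sigma_a > 0.0 and rng is not None:
        normals = rng.standard_normal(state.r.shape)
    r2, p2, a2, n2 = _step_numpy(state.r, state.p, state.a, state.n,
                                 normals, par, config.neighborhood)
    if not (np.isfinite(r2).all() and np.isfinite(p2).all()
            and np.isfinite(n2).all()):
        raise NumericalInstabilityError(
            "non-finite field values after step; reduce dt")
    return GridState(r=r2, p=p2, a=a2, n=n2,
                     t=state.t + par.dt, step=state.step + 1)


@dataclass
class _Recorder:
    times: list = field(default_factory=list)
    tot_r: list = field(default_factory=list)
    tot_p: list = field(default_factory=list)
    tot_n: list = field(default_factory=list)
    mean_a: list = field(default_factory=list)
    trace_a: list = field(default_factory=list)
    steps: list = field(default_factory=list)

    def record(self, step, t, tr, tp, tn, tap, trace_val, ncells):
        self.steps.append(step)
        self.times.append(t)
        self.tot_r.append(tr)
        self.tot_p.append(tp)
        self.tot_n.append(tn)
        # density-weighted mean affinity; plain 0 reference when empty
        self.mean_a.append(tap / tp if tp > 0 else np.nan)
        self.trace_a.append(trace_val)
        self._ncells = ncells


def run_pde(config: PDERunConfig, backend: str = "auto") -> RunResult:
    """Run the lattice simulation and collect per-step summaries.

    Records total r, p, n, the parasite-density-weighted mean affinity
    and the affinity at ``trace_point`` every ``trace_every`` steps,
    plus optional field snapshots.  Deterministic given ``config.seed``.

    ``backend`` is "numba", "numpy" or "auto" (numba when available);
    both backends produce bit-identical fields.
    """
    if backend == "auto":
        backend = "numba" if _kernels.HAVE_NUMBA else "numpy"
    if backend not in ("numba", "numpy"):
        raise ParameterError(f"unknown backend {backend!r}")
    par = config.params
    state = init_uniform(config)
    rng = np.random.default_rng(config.seed)
    ti, tj = (config.trace_point if config.trace_point is not None
              else (config.sizeX // 2, config.sizeY // 2))
    ncells = config.sizeX * config.sizeY
    rec = _Recorder()
    snapshots: dict[int, GridState] = {}
    use_noise = par.sigma_a > 0.0

    r, p, a, n = state.r, state.p, state.a, state.n
    r2 = np.empty_like(r)
    p2 = np.empty_like(p)
    a2 = np.empty_like(a)
    n2 = np.empty_like(n)
    normals = np.empty_like(r) if use_noise else None

    def summaries(rr, pp, aa, nn):
        return rr.sum(), pp.sum(), nn.sum(), float((aa * pp).sum())

    rec.record(0, 0.0, *summaries(r, p, a, n), a[ti, tj], ncells)
    if config.snapshot_every > 0:
        snapshots[0] = GridState(r.copy(), p.copy(), a.copy(), n.copy())

    for step in range(1, config.steps + 1):
        if use_noise:
            rng.standard_normal(out=normals)
        if backend == "numba":
            tr, tp, tn, tap = _kernels.pde_step_kernel(
                r, p, a, n, r2, p2, a2, n2,
                normals if use_noise else r,  # dummy array when unused
                use_noise,
                par.aR, par.dR, par.dP, par.m, par.n0, par.D, par.Dn,
                par.sigma_a, par.dt, par.a_min, par.a_max, P_FLOOR,
                config.neighborhood == "moore")
        else:
            r2, p2, a2, n2 = _step_numpy(r, p, a, n,
                                         normals if use_noise else None,
                                         par, config.neighborhood)
            tr, tp, tn, tap = summaries(r2, p2, a2, n2)
        if not (np.isfinite(tr) and np.isfinite(tp) and np.isfinite(tn)):
            raise NumericalInstabilityError(
                f"non-finite field values at step {step}; reduce dt")
        r, r2 = r2, r
        p, p2 = p2, p
        a, a2 = a2, a
        n, n2 = n2, n
        if step % config.trace_every == 0 or step == config.steps:
            rec.record(step, step * par.dt, tr, tp, tn, tap,
                       a[ti, tj], ncells)
        if config.snapshot_every > 0 and step % config.snapshot_every == 0:
            snapshots[step] = GridState(r.copy(), p.copy(), a.copy(),
                                        n.copy(), step * par.dt, step)

    result = RunResult(
        times=np.asarray(rec.times),
        steps=np.asarray(rec.steps),
        replicase_series=np.asarray(rec.tot_r) / ncells,
        parasite_series=np.asarray(rec.tot_p) / ncells,
        resource_series=np.asarray(rec.tot_n) / ncells,
        affinity_series=np.asarray(rec.mean_a),
        trace=np.asarray(rec.trace_a),
        snapshots=snapshots if snapshots else None,
        final_state=GridState(r, p, a, n, config.steps * par.dt,
                              config.steps),
    )
    result.outcome = classify_outcome(result, eps=config.extinction_eps)
    return result
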