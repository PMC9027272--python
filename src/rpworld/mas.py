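"""Discrete multi-agent simulator of the RP system.

RNA molecules are explicit agents (circles of radius ``agent_size``)
performing Brownian motion in a periodic arena.  Agents whose circles
intersect can react: a replicase copies an overlapping parasite with
the parasite's own probability kP, or an overlapping replicase with
the global probability kR; two parasites never react.  Spontaneous
decay is handled by pre-sampling a remaining life time (RLT) from the
geometric law equivalent to a per-step decay probability
``1 - exp(-d*dt)``.  Crowding kills: an agent with more than ``Nmax``
overlapping neighbours is removed.  Newly created parasites mutate
their kP with probability mP by a uniform shift in [-delta/2, delta/2].

The public helpers in this module are the reference (NumPy / pure
Python) implementations; :func:`run_mas` executes the same algorithm
through a compiled kernel for full-size runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .errors import ParameterError, RPWorldError
from .metrics import RunResult, classify_outcome
from .params import MASParams

__all__ = ["Agent", "Population", "decay_probability", "sample_rlt",
           "brownian_displacement", "find_neighbors",
           "attempt_replication", "mutate_kp", "mas_step", "run_mas"]

REPLICASE = "replicase"
PARASITE = "parasite"


@dataclass
class Agent:
    """One RNA molecule: position, kind, replication probability, RLT."""

    x: float
    y: float
    type: str
    kP: float = 0.0
    rlt: int = 1

    @property
    def is_replicase(self) -> bool:
        return self.type == REPLICASE


@dataclass
class Population:
    """Column-wise agent storage (struct of arrays)."""

    x: np.ndarray
    y: np.ndarray
    is_replicase: np.ndarray
    kP: np.ndarray
    rlt: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_replicases(self) -> int:
        return int(self.is_replicase.sum())

    @property
    def n_parasites(self) -> int:
        return int(len(self) - self.is_replicase.sum())

    def agent(self, i: int) -> Agent:
        return Agent(float(self.x[i]), float(self.y[i]),
                     REPLICASE if self.is_replicase[i] else PARASITE,
                     float(self.kP[i]), int(self.rlt[i]))

    @classmethod
    def empty(cls) -> "Population":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=bool),
                   np.empty(0), np.empty(0, dtype=np.int64))

    @classmethod
    def from_agents(cls, agents) -> "Population":
        agents = list(agents)
        return cls(
            x=np.array([a.x for a in agents], dtype=float),
            y=np.array([a.y for a in agents], dtype=float),
            is_replicase=np.array([a.is_replicase for a in agents],
                                  dtype=bool),
            kP=np.array([a.kP for a in agents], dtype=float),
            rlt=np.array([a.rlt for a in agents], dtype=np.int64),
        )

    @classmethod
    def initialize(cls, params: MASParams,
                   rng: np.random.Generator) -> "Population":
        """Uniform random positions; parasites all start at kP0."""
        ntot = params.n_replicases0 + params.n_parasites0
        x = rng.uniform(0.0, params.sizeX, ntot)
        y = rng.uniform(0.0, params.sizeY, ntot)
        is_rep = np.zeros(ntot, dtype=bool)
        is_rep[:params.n_replicases0] = True
        kp = np.where(is_rep, 0.0, params.kP0)
        u = 1.0 - rng.random(ntot)
        rlt = sample_rlt(params.d, params.dt, u)
        return cls(x=x, y=y, is_replicase=is_rep, kP=kp, rlt=rlt)


def decay_probability(d: float, dt: float) -> float:
    """Per-step probability of spontaneous decay, 1 - exp(-d*dt)."""
    if d < 0 or dt < 0:
        raise ParameterError("d and dt must be >= 0")
    return -math.expm1(-d * dt)


def sample_rlt(d: float, dt: float, x):
    """Remaining life time floor(-ln(x)/(d*dt)) + 1 for uniform x in (0,1].

    Statistically equivalent to a per-step Bernoulli decay with
    probability ``decay_probability(d, dt)`` (geometric lifetimes).
    Accepts a scalar or an array of draws.
    """
    if d * dt <= 0:
        raise ParameterError("sample_rlt requires d*dt > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x > 1.0):
        raise ParameterError("x must lie in (0, 1]")
    out = (np.floor(-np.log(x) / (d * dt)) + 1).astype(np.int64)
    return out if out.ndim else int(out)


def brownian_displacement(D: float, dt: float, xi) -> np.ndarray:
    """Brownian step sqrt(2*D*dt) * xi for a standard-normal vector xi."""
    if D < 0 or dt < 0:
        raise ParameterError("D and dt must be >= 0")
    return math.sqrt(2.0 * D * dt) * np.asarray(xi, dtype=float)


def find_neighbors(focal: int, population: Population,
                   params: MASParams) -> np.ndarray:
    """Indices of agents whose circles intersect the focal agent's.

    Overlap means centre-to-centre distance strictly below
    ``2*agent_size`` under the periodic minimum-image convention.  Uses
    a spatial tree; must (and does, see tests) agree with the all-pairs
    computation.
    """
    radius = 2.0 * params.agent_size
    pts = np.column_stack([population.x % params.sizeX,
                           population.y % params.sizeY])
    tree = cKDTree(pts, boxsize=(params.sizeX, params.sizeY))
    cand = tree.query_ball_point(pts[focal], r=radius)
    out = []
    for j in cand:
        if j == focal:
            continue
        if _torus_dist2(pts[focal], pts[j],
                        params.sizeX, params.sizeY) < radius * radius:
            out.append(j)
    return np.array(sorted(out), dtype=np.int64)


def _torus_dist2(p1, p2, sizeX, sizeY) -> float:
    dx = p2[0] - p1[0]
    dx -= sizeX * round(dx / sizeX)
    dy = p2[1] - p1[1]
    dy -= sizeY * round(dy / sizeY)
    return dx * dx + dy * dy


def attempt_replication(xi: Agent, nj: Agent, params: MASParams,
                        rng: np.random.Generator) -> Agent | None:
    """Resolve one overlapping pair; return the offspring or None.

    Two parasites never react.  In a replicase-parasite pair the
    parasite is always the template and its kP is the reaction
    probability.  For two replicases the neighbour ``nj`` serves as
    template with probability kR.  The offspring is an exact copy of
    the template at the template's position with a freshly sampled RLT;
    new parasites are then subjected to kP mutation (replicases never
    mutate here, their kind cannot change in this reaction).
    """
    if xi.is_replicase:
        template, prob = (nj, params.kR) if nj.is_replicase else (nj, nj.kP)
    elif nj.is_replicase:
        template, prob = xi, xi.kP
    else:
        return None
    if rng.random() >= prob:
        return None
    u = 1.0 - rng.random()
    child = Agent(template.x, template.y, template.type, template.kP,
                  sample_rlt(params.d, params.dt, u))
    if not child.is_replicase:
        child.kP = mutate_kp(child.kP, params, rng)
    return child


def mutate_kp(kP: float, params: MASParams,
              rng: np.random.Generator) -> float:
    """With probability mP shift kP by U(-delta/2, delta/2), clamp [0,1]."""
    if not 0.0 <= kP <= 1.0:
        raise ParameterError("kP must lie in [0, 1]")
    if rng.random() < params.mP:
        kP = kP + rng.uniform(-params.delta / 2.0, params.delta / 2.0)
        kP = min(1.0, max(0.0, kP))
    return kP


def mas_step(population: Population, params: MASParams,
             rng: np.random.Generator) -> Population:
    """One full simulation step (pure-Python reference path).

    Order of events: decrement every RLT and remove expired agents;
    shuffle the processing order; then per agent collect the overlap
    set, die of crowding if it exceeds Nmax, otherwise move and attempt
    one reaction per overlapping neighbour.  Offspring join the
    population immediately (they can be neighbours later in the same
    step) but only act from the next step.
    """
    agents = [population.agent(i) for i in range(len(population))]
    for ag in agents:
        ag.rlt -= 1
    agents = [ag for ag in agents if ag.rlt > 0]
    order = list(rng.permutation(len(agents)))
    alive = [True] * len(agents)
    radius2 = (2.0 * params.agent_size) ** 2
    step_sd = math.sqrt(2.0 * params.D * params.dt)
    for i in order:
        if not alive[i]:
            continue
        xi = agents[i]
        nbrs = [j for j in range(len(agents))
                if j != i and alive[j]
                and _torus_dist2((xi.x, xi.y),
                                 (agents[j].x, agents[j].y),
                                 params.sizeX, params.sizeY) < radius2]
        if len(nbrs) > params.Nmax:
            alive[i] = False
            continue
        nbrs = list(rng.permutation(nbrs)) if nbrs else []
        xi.x = (xi.x + step_sd * rng.standard_normal()) % params.sizeX
        xi.y = (xi.y + step_sd * rng.standard_normal()) % params.sizeY
        for j in nbrs:
            if not alive[j]:
                continue
            child = attempt_replication(xi, agents[j], params, rng)
            if child is not None:
                agents.append(child)
                alive.append(True)
    return Population.from_agents(
        ag for ag, ok in zip(agents, alive) if ok)


def run_mas(params: MASParams, capacity: int | None = None) -> RunResult:
    """Run the agent simulation until ``time_limit`` or one species dies.

    Returns per-step replicase/parasite counts and the mean/min/max kP
    of living parasites.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    pop0 = Population.initialize(params, rng)
    n_init = len(pop0)
    if capacity is None:
        radius = 2.0 * params.agent_size
        # crowding (Nmax neighbours in a disc of the interaction radius)
        # bounds the sustainable density; 4x head-room for transients
        dens_cap = (params.Nmax + 1) / (math.pi * radius * radius)
        capacity = int(min(4.0 * dens_cap * params.sizeX * params.sizeY,
                           2_000_000))
        capacity = max(capacity, 4 * n_init + 1024)
    x = np.empty(capacity)
    y = np.empty(capacity)
    rep = np.zeros(capacity, dtype=np.uint8)
    kp = np.zeros(capacity)
    rlt = np.zeros(capacity, dtype=np.int64)
    alive = np.zeros(capacity, dtype=np.uint8)
    x[:n_init] = pop0.x
    y[:n_init] = pop0.y
    rep[:n_init] = pop0.is_replicase
    kp[:n_init] = pop0.kP
    rlt[:n_init] = pop0.rlt
    alive[:n_init] = 1

    out_nr = np.zeros(params.time_limit + 1, dtype=np.int64)
    out_np = np.zeros(params.time_limit + 1, dtype=np.int64)
    out_mean = np.full(params.time_limit + 1, np.nan)
    out_min = np.full(params.time_limit + 1, np.nan)
    out_max = np.full(params.time_limit + 1, np.nan)

    _kernels.seed_rng(int(np.random.SeedSequence(params.seed)
                          .generate_state(1, np.uint32)[0]))
    n_rec, n_tot, status = _kernels.mas_run_kernel(
        x, y, rep, kp, rlt, alive, n_init,
        float(params.sizeX), float(params.sizeY),
        2.0 * params.agent_size, params.Nmax, params.d, params.kR,
        params.dt, params.D, params.delta, params.mP, params.time_limit,
        out_nr, out_np, out_mean, out_min, out_max)
    if status == 1:
        raise RPWorldError("agent capacity exceeded; pass a larger capacity")
    if status == 2:
        raise RPWorldError("spatial-bin capacity exceeded")

    live = alive[:n_tot].astype(bool)
    final = Population(x=x[:n_tot][live].copy(), y=y[:n_tot][live].copy(),
                       is_replicase=rep[:n_tot][live].astype(bool),
                       kP=kp[:n_tot][live].copy(),
                       rlt=rlt[:n_tot][live].copy())
    times = np.arange(n_rec) * params.dt
    result = RunResult(
        times=times,
        steps=np.arange(n_rec),
        replicase_series=out_nr[:n_rec].astype(float),
        parasite_series=out_np[:n_rec].astype(float),
        affinity_series=out_mean[:n_rec],
        affinity_min_series=out_min[:n_rec],
        affinity_max_series=out_max[:n_rec],
        final_state=final,
    )
    result.outcome = classify_outcome(result, eps=0.5)
    return result
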