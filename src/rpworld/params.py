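"""Parameter containers for the replicase-parasite (RP) model.

Two observation scales share one chemistry: a macroscopic
reaction-diffusion description over densities (``PDEParams``) and a
microscopic Brownian-dynamics agent description (``MASParams``).  The
defaults are the model's tabulated global parameter sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

from .errors import ParameterError


@dataclass(frozen=True)
class PDEParams:
    """Rates and constants of the continuous (density) RP model.

    Attributes
    ----------
    aR : float
        Replicase affinity towards replicases (reaction rate of the
        third-order replication reaction, per density^2 per time).
    aP0 : float
        Initial / fixed parasite affinity.  In runs with mutation the
        affinity field starts uniform at this value; in the analytic
        module this is the constant aP unless overridden per call.
    dR, dP : float
        First-order decay rates of replicases and parasites (per time).
        Both default to the single decay rate d of the reference
        parameter table; they are kept separate because the balance
        equations distinguish them.
    m : float
        Miscopy probability: chance that copying a replicase yields a
        parasite instead (dimensionless, in [0, 1]).
    n0 : float
        Constant resource production rate (density per time).
    D : float
        Diffusion constant of all RNA species (grid units^2 per time;
        the lattice spacing is 1, so D absorbs the spacing).
    Dn : float
        Diffusion constant of the resource.
    sigma_a : float
        Magnitude of the random affinity mutation term.  The per-step
        perturbation of the local mean affinity has standard deviation
        ``sigma_a * sqrt(dt) / sqrt(p)`` — mutation pressure is
        inversely proportional to the square root of the local parasite
        density (large populations evolve slowly).
    dt : float
        Integration time step.
    a_min, a_max : float
        Clamp bounds for the affinity field.  Affinity is interpreted as
        a replication efficiency, matching the agent model's
        replication probability, hence [0, 1].
    """

    aR: float = 1.0
    aP0: float = 1.0
    dR: float = 0.01
    dP: float = 0.01
    m: float = 0.0
    n0: float = 1.0
    D: float = 5.0
    Dn: float = 10.0
    sigma_a: float = 0.05
    dt: float = 0.1
    a_min: float = 0.0
    a_max: float = 1.0

    def __post_init__(self):
        for name in ("aR", "aP0", "dR", "dP", "n0", "D", "Dn", "sigma_a"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.m <= 1.0:
            raise ParameterError("m must lie in [0, 1]")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if not self.a_min <= self.aP0 <= self.a_max:
            raise ParameterError("aP0 must lie in [a_min, a_max]")

    def replace(self, **kw) -> "PDEParams":
        d = asdict(self)
        d.update(kw)
        return PDEParams(**d)


@dataclass(frozen=True)
class PDERunConfig:
    """Lattice geometry and bookkeeping for a PDE run."""

    params: PDEParams = field(default_factory=PDEParams)
    sizeX: int = 256
    sizeY: int = 256
    steps: int = 0
    seed: int = 0
    boundary: str = "periodic"
    neighborhood: str = "moore"
    snapshot_every: int = 0          # 0 = no snapshots
    trace_point: tuple[int, int] | None = None  # default: centre cell
    trace_every: int = 1
    extinction_eps: float = 1e-6

    def __post_init__(self):
        if self.sizeX < 1 or self.sizeY < 1:
            raise ParameterError("sizeX, sizeY must be >= 1")
        if self.steps < 0:
            raise ParameterError("steps must be >= 0")
        if self.boundary != "periodic":
            raise ParameterError("only periodic boundaries are implemented")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ParameterError("neighborhood must be moore or von_neumann")
        if self.trace_every < 1:
            raise ParameterError("trace_every must be >= 1")
        tp = self.trace_point
        if tp is not None:
            i, j = tp
            if not (0 <= i < self.sizeX and 0 <= j < self.sizeY):
                raise ParameterError("trace_point outside the lattice")


@dataclass(frozen=True)
class MASParams:
    """Global parameters of the Brownian-dynamics agent simulation.

    Defaults follow the reference agent-model parameter table: arena
    800x800, agent radius 3.0, crowding cap 4 neighbours, decay rate
    0.1, replicase-replicase reaction probability kR = 1.0, dt = 1.0,
    diffusion constant 15.0, mutation half-range delta/2 = 0.05 applied
    with probability mP = 0.1.
    """

    sizeX: float = 800.0
    sizeY: float = 800.0
    agent_size: float = 3.0
    Nmax: int = 4
    d: float = 0.1
    kR: float = 1.0
    dt: float = 1.0
    D: float = 15.0
    delta: float = 0.1
    mP: float = 0.1
    n_replicases0: int = 2000
    n_parasites0: int = 2000
    kP0: float = 0.5
    seed: int = 0
    time_limit: int = 2000

    def __post_init__(self):
        if self.sizeX <= 0 or self.sizeY <= 0:
            raise ParameterError("arena size must be positive")
        if self.agent_size <= 0:
            raise ParameterError("agent_size must be positive")
        if self.Nmax < 0:
            raise ParameterError("Nmax must be >= 0")
        for name in ("kR", "mP", "kP0"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.d < 0 or self.D < 0 or self.delta < 0:
            raise ParameterError("d, D, delta must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.n_replicases0 < 0 or self.n_parasites0 < 0:
            raise ParameterError("initial counts must be >= 0")
        if self.time_limit < 0:
            raise ParameterError("time_limit must be >= 0")

    def replace(self, **kw) -> "MASParams":
        d = asdict(self)
        d.update(kw)
        return MASParams(**d)


def _from_mapping(cls, mapping):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def pde_config_from_json(path_or_str) -> PDERunConfig:
    """Load a :class:`PDERunConfig` from a JSON file path or JSON string.

    The JSON object holds the run-level keys plus a nested ``params``
    object (or PDEParams keys inlined at top level).
    """
    obj = _load_json(path_or_str)
    pkeys = {f.name for f in fields(PDEParams)}
    raw_params = obj.pop("params", {})
    for k in list(obj):
        if k in pkeys:
            raw_params[k] = obj.pop(k)
    params = _from_mapping(PDEParams, raw_params)
    if "trace_point" in obj and obj["trace_point"] is not None:
        obj["trace_point"] = tuple(obj["trace_point"])
    return _from_mapping(PDERunConfig, {"params": params, **obj})


def mas_params_from_json(path_or_str) -> MASParams:
    obj = _load_json(path_or_str)
    return _from_mapping(MASParams, obj)


def _load_json(path_or_str):
    s = str(path_or_str)
    if s.lstrip().startswith("{"):
        return json.loads(s)
    with open(s) as fh:
        return json.load(fh)
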