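# Methods

`rpworld` models an RNA-world population of two molecular species —
**replicases** `r`, which catalyse the copying of any template
including themselves, and **parasites** `p`, which are copied but
catalyse nothing — competing for an abiotically produced resource `n`.
The same chemistry is implemented at two observation scales: a
macroscopic reaction–diffusion lattice over densities, and a
microscopic Brownian-dynamics agent simulation.  A closed-form
well-mixed analysis links the two.

## The density model

Replication is a third-order mass-action reaction (replicase +
template + resource), decay is first order, the resource is produced
at a constant rate `n0` and diffuses, and every copy of a replicase
has probability `m` of coming out as a parasite (miscopy).  With
affinities `aR` (replicase as template) and `aP` (parasite as
template):

    dn/dt = n0 − n·r·(aR·r + aP·p)           + Dn ∇²n
    dr/dt = (1−m)·aR·n·r²       − dR·r       + D ∇²r
    dp/dt = m·aR·n·r² + aP·n·r·p − dP·p      + D ∇²p

### Well-mixed equilibrium and the persistence inequality

Setting time and space derivatives to zero and assuming `0 < m < 1`
gives a unique interior equilibrium

    A = m·aR·dR / (dP·(1−m)·aR − aP·dR),   p = A·r,
    n = dR²·(aR + aP·A) / (n0·((1−m)·aR)²),
    r = dR / ((1−m)·aR·n),

which exists iff the **persistence inequality**
`1 − m > aP·dR/(aR·dP)` holds.  `persistence_margin` returns the
signed slack of this inequality.  At `m = 0` the equilibrium is
degenerate: coexistence at any ratio iff `aR·dP = aP·dR`, otherwise no
mixed equilibrium at all; `steady_state` signals this with a dedicated
exception carrying the knife-edge flag.  At `m = 1` replication is
ineffective and no equilibrium exists.

Existence is not stability: the linearization of the replicase
equation at the equilibrium has the positive coefficient
`(1−m)·aR·n·r` (`linear_growth_rate`), so replicase perturbations are
locally amplified and a nonlinear argument is needed.

### The pendulum reduction

With the parasite density frozen at a value `p` (flag `clamp_p` of
`integrate_well_mixed`), the substitution `y = 1/r` and elimination of
`n` turn the replicase–resource subsystem into

    y'' = P(y) + Q(y)·y',
    P(y) = dR·aP·p − n0·(1−m)·aR + dR·aR/y,
    Q(y) = dR − aP·p/y − aR/y².

`P` is a force with the single root `yE = dR·aR/(n0(1−m)aR − dR·aP·p)`
(positive iff `p < n0(1−m)aR/(dR·aP)`), decreasing through it; `Q` is
a friction coefficient, non-positive up to the critical point
`yC = (aP·p + sqrt(aP²p² + 4·aR·dR))/(2·dR)` and positive beyond.
Below `yC` the system is a damped pendulum and settles at `yE`; past
`yC` friction pumps energy in and `y → ∞`, i.e. the replicase
population collapses.  The equilibrium is only attracting when
`yE < yC`; parameter sets whose equilibrium falls at or beyond the
critical point satisfy the persistence inequality yet collapse (the
property suite exercises this distinction).

Freezing `p` is an approximation with no closed-form validity bound;
it is exposed as a flag rather than silently applied, and the
equivalence `y(t) = 1/r(t)` is verified against the clamped well-mixed
integrator to 1e−3 relative.

### Numerics of the analytic module

Both analytic integrators use fixed-step classical RK4 (compiled
inner loops), default `dt = 0.1` matching the lattice step; negative
densities are clamped to 0 after each step, mirroring the lattice
scheme's clamp.  `integrate_pendulum` truncates with a divergence flag
once `y > 1e6·yE` (the collapse regime has no finite limit) or `y ≤ 0`
(outside the domain of the reduction).  The well-mixed system becomes
stiff when the equilibrium consumption coefficient `r·(aR·r + aP·p)`
is large against `1/dt`; tests pick parameter sets (or shrink `dt`)
accordingly — RK4 is used for oracle accuracy, not stiffness.

## The lattice simulator

Forward Euler on a torus with lattice spacing 1 (diffusion constants
absorb the spacing), four fields per cell: `r`, `p`, `n` and the local
mean parasite affinity `a`.  Per step and cell, in order:

1. `new_r = aR·Δt·r²·(1−m)·n`, `new_p = Δt·r·(aR·r·m + a·p)·n`;
2. if `new_r + new_p > n`, both are rescaled by `n/(new_r+new_p)`
   (resource limitation: a cell cannot consume more than it holds);
3. fields update with growth, decay, production and diffusion
   `f + D·Δt·(avg(f) − f)`;
4. the affinity field advects as the conserved mass `a·p`, and the
   local mean is recovered as transported mass over transported
   carrier density (see below);
5. `a` receives a Gaussian mutation kick of standard deviation
   `sigma_a·sqrt(Δt)/sqrt(max(p, 1e−12))` — mutation moves the local
   mean more slowly where the population carrying it is large;
6. negative densities clamp to 0, `a` clamps to `[a_min, a_max]`.

Design choices that were genuinely open:

- **Neighbourhood.**  "Adjacent neighbours" is read as the 8-cell
  Moore ring.  The 4-cell von Neumann cross (also implemented) is
  marginally unstable at the default resource diffusion `Dn·Δt = 1.0`:
  the chequerboard mode has amplification factor `1 − 2·D·Δt = −1`,
  and the clamp at 0 rectifies it into a growing artefact (observed:
  the resource field splits into a 0/huge chequerboard and the
  replicase field blows up by four orders of magnitude).  Over the
  Moore ring the chequerboard averages to zero, making the update
  stable up to `D·Δt = 1`.
- **Affinity renormalization.**  The transported affinity mass
  `a·p + D·Δt·(avg(a·p) − a·p)` is divided by the *equally
  transported* parasite density `p + D·Δt·(avg(p) − p)`.  Growth and
  decay copy or remove carriers without changing the local mean, so
  only the transport operator may enter this quotient.  This choice
  conserves total affinity mass exactly under pure transport and
  gives newly recolonized cells the mass-weighted mean affinity of
  their immigrants; dividing by the pre-step density instead (a
  plausible literal reading of the update order) breaks both.
- **Boundary.**  Periodic (torus) — the standard choice for
  pattern-formation studies; only `periodic` is implemented.
- **Clamp bounds.**  `a_min = 0` (negative affinity is meaningless and
  the scheme clamps all negative variables); `a_max` defaults to 1.0,
  reading the affinity as a replication efficiency on the same scale
  as the agent model's replication probability kP.  The clamp matters:
  parasites can locally out-replicate replicases only where
  `a > aR·dP/dR·(1−m)`, so with `aR = 1`, equal decay rates and
  `a_max = 1` parasite-driven replicase collapse is impossible by
  construction.  `a_max` is an ordinary parameter for studying that
  regime.
- **Mutation magnitude.** `sigma_a` defaults to 0.05 (affinity units
  per square-root time).  The continuous theory fixes only the form
  of the noise, not its magnitude; see "Known limitations" for how
  strongly the qualitative behaviour depends on it.
- **Decay rates.** `dR` and `dP` both default to the single tabulated
  decay rate 0.01 but are independently configurable, since the
  balance equations distinguish them.
- **Extinction threshold.** A species with mean density below 1e−6 is
  labelled extinct for outcome classification.

Both a vectorized NumPy step and a compiled kernel implement the
update with identical operation order; the two are bit-identical and
the test suite asserts it.  Runs are deterministic given the seed.

## The agent simulator

Agents are circles of radius `agent_size` (default 3.0) in a periodic
arena (default 800×800), each with a position, a kind (replicase or
parasite), a replication probability `kP` (parasites), and a
pre-sampled remaining lifetime (RLT).  Per step, per Algorithm order:

1. every RLT decrements; agents reaching 0 are removed.  RLT is drawn
   at birth as `floor(−ln(X)/(d·Δt)) + 1` with `X ~ U(0,1]`, the
   inverse-CDF sample of the geometric law with per-step death
   probability `1 − exp(−d·Δt)` — statistically identical to flipping
   the decay coin every step, but cheaper;
2. agents are processed in a freshly shuffled order.  Each collects
   its overlap set (centre distance strictly below `2·agent_size`,
   minimum-image convention); an agent with more than `Nmax`
   neighbours dies of crowding — the model's only density limitation;
3. the survivor moves by `sqrt(2·D·Δt)·ξ` with `ξ` standard normal
   per axis, then attempts one reaction per (shuffled) neighbour:
   two parasites never react; in a replicase–parasite pair the
   parasite is always the template and its own `kP` the success
   probability; for two replicases the neighbour is the template with
   probability `kR`.  Offspring are exact copies placed at the
   template's current position with a fresh RLT; new parasites mutate
   `kP` with probability `mP` by `U(−δ/2, +δ/2)`, clamped to [0, 1].
   Offspring are physically present immediately (they count as
   neighbours and toward crowding later in the same step) but act
   only from the next step.

Open points resolved here: the arena wraps periodically (consistent
with the lattice torus); the overlap threshold is strict (ties are
measure-zero); for replicase–replicase pairs the neighbour serves as
template (symmetric in distribution because pair order is shuffled);
an agent may participate in several reactions within one step; a
reaction partner consumed as template remains available to other
pairs.  A run ends at `time_limit` or as soon as either species count
is zero; the outcome label is "Alive" iff both species are present at
the time limit.

The engine is a compiled kernel over flat arrays with a cell-list
spatial index (cells no smaller than the interaction radius, so the
3×3 cell patch covers every candidate); the public helpers
(`find_neighbors`, `attempt_replication`, `mas_step`, ...) are plain
NumPy/Python and serve as the reference semantics in the tests, with
the tree-based neighbour search checked against the all-pairs
computation.

## Metrics

`classify_outcome` labels a run from the final values of both species
series against a threshold (0.5 for counts, the extinction eps for
densities); it is invariant to rescaling the series.
`trace_statistics` reports extrema and mean of the post-burn-in
window (default burn-in: the first half, discarding the transient
away from the uniform start) and estimates an oscillation period as
the mean spacing of autocorrelation peaks, flagged undefined when no
peak has sufficient prominence.  `wave_condition` evaluates the
persistence-by-waves inequality `π(vT)² ≥ P`: a regrowth nucleus
travelling at front speed `v` for one cycle period `T` must cover at
least the minimal regrowth area `P`.  All three of `v`, `T`, `P` are
measured or user-supplied; the model does not predict them.

## Problem sizes used in the checks

The reference study conditions run the lattice at 1000×1000 and the
arena at 800×800.  The packaged checks run at desk scale, chosen so
every qualitative regime they probe is already expressed: steady-state
residuals are grid-free; the ODE-limit checks use 1×1 and 32×32
lattices over 1e4 steps; the agent-law checks use 1e4–1e5 draws; the
scenario sweep uses a 400×400 arena with 500+500 agents, 5 seeds and
2000 steps per cell; the affinity-band run uses a 256×256 lattice for
2e5 steps sampled every 100 steps.

## What the checks do and do not show

The synthetic runs start from the uniform state the study prescribes
(all fields 1.0) with the tabulated global parameters; they are not
fitted to any empirical data.  Passing the ODE-limit and pendulum
checks shows the three implementations (closed form, lattice, agent
engine) are mutually consistent, not that the RP model describes any
real prebiotic chemistry.  The agent-regime check shows the diffusion
and mutation-rate dependence of survival at a reduced scale; absolute
survival times at full scale may differ.

## Known limitations

- The lattice model is deterministic in the densities; populations
  never reach exact zero by decay alone ("atto-densities" persist and
  can reignite), unlike the agent model where extinction is genuine.
  This makes spatial boom–bust patterns much harder to nucleate on
  small uniform lattices than in the agent model: with the default
  mutation magnitude the affinity field stays nearly homogeneous (the
  per-step transport mixes ~half of a cell's deviation into its
  neighbours while the mutation kick at realistic densities moves it
  by well under 1%), and the lattice evolves as an almost well-mixed
  system.  A rough linear estimate makes this quantitative: ecological
  growth rates here are of order 1e-3 to 1e-2 per unit time while a
  perturbation of wavenumber k is damped at D·k², so only wavelengths
  above roughly 140 cells can grow — a 1000×1000 lattice fits many
  such modes, a 256×256 lattice marginally one.  Desk-scale lattice
  runs therefore reproduce the well-mixed regimes sharply but cannot
  express the heterogeneous travelling-wave regime of the full-scale
  study: with mutation on and the default [0, 1] affinity clamp the
  parasite affinity sits just below the replicase affinity and the
  parasite field slowly dies out; with the clamp lifted the mean
  affinity settles a few percent above it and the replicase field
  dies instead.  The affinity-band quantities reported by
  `scripts/acceptance.py` are computed from the faithful desk-scale
  run and reflect this regime, not the full-scale oscillation band.
- 3D lattices, implicit or adaptive solvers, replication complexes
  and sequence-bearing agents are out of scope.
- The pendulum reduction's clamped-parasite assumption has no
  quantitative validity bound; the package only verifies the exactly
  clamped case.
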