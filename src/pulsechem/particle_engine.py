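"""Step-by-step Brownian-dynamics engine with periodic boundary conditions.

The non-homogeneous chemical stage is simulated particle by particle: each
species performs isotropic Gaussian diffusion jumps (per-axis standard
deviation sqrt(2 D dt)) and a reaction fires whenever two compatible
reactants come within the reaction radius of their reaction.

Two periodic boundary conditions make the cubic box behave as one voxel of
an infinite lattice:

* **position wrapping** — a particle leaving the box re-enters through the
  opposite face (coordinates folded into [-L/2, L/2) per axis);
* **minimum image** — pair distances for the reaction test use the nearest
  periodic image, valid as long as 2R < L for every reaction radius R.

Neighbor search uses a periodic k-d tree queried at the largest reaction
radius; a brute-force O(n^2) pairing is kept as a cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chemistry import ChemicalSystem, validate_system

__all__ = [
    "SimulationBox",
    "ParticleState",
    "ReactionEvent",
    "wrap_position",
    "minimum_image",
    "diffusion_step",
    "reaction_sweep",
    "brute_force_candidate_pairs",
    "run_sbs",
    "graded_schedule",
]

#: Isotropic jitter (m) applied to co-located reaction products.
PRODUCT_JITTER = 1.0e-10


@dataclass(frozen=True)
class SimulationBox:
    """Cubic box of side L centred on the origin, coordinates in [-L/2, L/2)."""

    side_length: float  # m

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("box side must be positive")

    @property
    def volume_m3(self) -> float:
        return self.side_length**3

    @property
    def volume_litre(self) -> float:
        return self.volume_m3 * 1.0e3


@dataclass
class ParticleState:
    """Positions (m) and species indices of every live particle."""

    positions: np.ndarray  # (n, 3)
    species: np.ndarray  # (n,) int, indices into system.species
    time: float = 0.0

    @classmethod
    def empty(cls, time: float = 0.0) -> "ParticleState":
        return cls(np.empty((0, 3)), np.empty(0, dtype=np.int64), time)

    @property
    def n(self) -> int:
        return len(self.species)

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.species.copy(), self.time)

    def counts(self, n_species: int) -> np.ndarray:
        return np.bincount(self.species, minlength=n_species)

    def merge(self, other: "ParticleState") -> "ParticleState":
        return ParticleState(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.species, other.species]),
            self.time,
        )


@dataclass
class ReactionEvent:
    reaction_id: str
    time: float
    position: np.ndarray


def wrap_position(x: np.ndarray | float, L: float):
    """Fold coordinates into [-L/2, L/2) (periodic re-entry on exit)."""
    return (np.asarray(x) + 0.5 * L) % L - 0.5 * L


def minimum_image(dx: np.ndarray | float, L: float):
    """Displacement to the nearest periodic image, per component in [-L/2, L/2]."""
    dx = np.asarray(dx)
    return dx - L * np.floor(dx / L + 0.5)


def diffusion_step(
    state: ParticleState,
    dt: float,
    rng: np.random.Generator,
    diffusion: np.ndarray,
    box: SimulationBox,
) -> None:
    """Advance every particle by one Gaussian jump (in place) and re-wrap."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.n:
        sigma = np.sqrt(2.0 * diffusion[state.species] * dt)
        state.positions += rng.standard_normal(state.positions.shape) * sigma[:, None]
        state.positions = wrap_position(state.positions, box.side_length)
    state.time += dt


def brute_force_candidate_pairs(
    positions: np.ndarray, box: SimulationBox, r_max: float
) -> np.ndarray:
    """All unordered index pairs with minimum-image distance <= r_max (oracle)."""
    n = len(positions)
    pairs = []
    for i in range(n):
        d = minimum_image(positions[i + 1 :] - positions[i], box.side_length)
        dist = np.linalg.norm(d, axis=1)
        for off in np.nonzero(dist <= r_max)[0]:
            pairs.append((i, i + 1 + off))
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def _candidate_pairs(positions: np.ndarray, box: SimulationBox, r_max: float) -> np.ndarray:
    """Periodic k-d tree neighbor pairs within r_max."""
    L = box.side_length
    shifted = (positions + 0.5 * L) % L
    # boxsize requires points strictly inside [0, L)
    shifted[shifted >= L] = 0.0
    tree = cKDTree(shifted, boxsize=L)
    return tree.query_pairs(r_max, output_type="ndarray")


def reaction_sweep(
    state: ParticleState,
    system: ChemicalSystem,
    box: SimulationBox,
    rng: np.random.Generator,
    event_log: list[ReactionEvent] | None = None,
    use_brute_force: bool = False,
    candidate_pairs: np.ndarray | None = None,
) -> ParticleState:
    """Fire every reaction whose reactants lie within the reaction radius.

    Candidate pairs are resolved greedily nearest-first (ties broken at
    random) so that each particle reacts at most once per sweep.  Reactants
    are removed; products are placed at the diffusion-weighted midpoint of
    the pair (weight of reactant A proportional to sqrt(D_B), i.e. products
    appear closer to the slower reactant), multiple products with a small
    isotropic jitter.  Returns the new state; events are appended to
    ``event_log`` if given.
    """
    if state.n < 2:
        return state
    radii = np.array([r.reaction_radius for r in system.reactions])
    r_max = float(radii.max()) if len(radii) else 0.0
    if r_max == 0.0:
        return state
    if 2.0 * r_max >= box.side_length:
        raise ValueError("2R >= L: minimum-image convention violated")

    L = box.side_length
    if candidate_pairs is not None:
        pairs = candidate_pairs
    elif use_brute_force:
        pairs = brute_force_candidate_pairs(state.positions, box, r_max)
    else:
        pairs = _candidate_pairs(state.positions, box, r_max)
    if len(pairs) == 0:
        return state

    # distance filter, vectorized over the (few) candidate pairs
    sp = state.species
    pi, pj = pairs[:, 0], pairs[:, 1]
    d = minimum_image(state.positions[pj] - state.positions[pi], L)
    dist_all = np.linalg.norm(d, axis=1)
    keep = []
    dists = []
    reactions = []
    close = np.nonzero(dist_all <= r_max)[0]
    for idx in close:
        i, j = int(pi[idx]), int(pj[idx])
        key = (min(sp[i], sp[j]), max(sp[i], sp[j]))
        rlist = system.pair_index.get(key)
        if not rlist:
            continue
        for r in rlist:
            if dist_all[idx] <= r.reaction_radius:
                keep.append((i, j))
                dists.append(dist_all[idx])
                reactions.append(r)
                break
    if not keep:
        return state

    order = np.lexsort((rng.random(len(keep)), np.asarray(dists)))
    consumed = np.zeros(state.n, dtype=bool)
    new_pos = []
    new_sp = []
    sqrt_d = np.sqrt(system.diffusion_array())
    for idx in order:
        i, j = keep[idx]
        if consumed[i] or consumed[j]:
            continue
        consumed[i] = consumed[j] = True
        r = reactions[idx]
        xi, xj = state.positions[i], state.positions[j]
        dij = minimum_image(xj - xi, L)
        wi, wj = sqrt_d[sp[i]], sqrt_d[sp[j]]
        # product sits nearer the slower reactant
        frac = wi / (wi + wj) if (wi + wj) > 0 else 0.5
        midpoint = wrap_position(xi + frac * dij, L)
        n_prod = len(r.products)
        for name in r.products:
            pos = midpoint
            if n_prod > 1:
                pos = wrap_position(midpoint + rng.standard_normal(3) * PRODUCT_JITTER, L)
            new_pos.append(pos)
            new_sp.append(system.index[name])
        if event_log is not None:
            event_log.append(ReactionEvent(r.id, state.time, midpoint.copy()))

    survivors = ~consumed
    positions = state.positions[survivors]
    species = sp[survivors]
    if new_pos:
        positions = np.vstack([positions, np.array(new_pos)])
        species = np.concatenate([species, np.array(new_sp, dtype=np.int64)])
    return ParticleState(positions, species, state.time)


@dataclass
class TimeStepSchedule:
    """Piecewise-constant, log-graded time-step schedule.

    ``phases`` is a list of (t_until, dt); the step size dt applies while
    the simulation time is below t_until.
    """

    phases: list[tuple[float, float]] = field(
        default_factory=lambda: graded_schedule().phases
    )

    def dt_at(self, t: float) -> float:
        for t_until, dt in self.phases:
            if t < t_until:
                return dt
        return self.phases[-1][1]


def graded_schedule(dt_min: float = 1.0e-12, dt_max: float = 1.0e-7) -> TimeStepSchedule:
    """Decade-graded schedule: dt_min up to 1e4*dt_min of elapsed time, then
    one decade coarser per decade of time, capped at dt_max."""
    phases = []
    dt = dt_min
    t_until = dt_min * 1.0e4
    while dt < dt_max:
        phases.append((t_until, dt))
        dt *= 10.0
        t_until *= 10.0
    phases.append((np.inf, dt_max))
    return TimeStepSchedule(phases)


def run_sbs(
    initial: ParticleState,
    system: ChemicalSystem,
    box: SimulationBox,
    t_end: float,
    rng: np.random.Generator,
    schedule: TimeStepSchedule | None = None,
    injections: list[tuple[float, ParticleState]] | None = None,
    sample_times: np.ndarray | None = None,
    event_log: list[ReactionEvent] | None = None,
    engine: str = "fast",
) -> tuple[pd.DataFrame, ParticleState]:
    """Alternate diffusion jumps and reaction sweeps up to ``t_end``.

    ``injections`` is a list of (time, ParticleState delta) merged into the
    simulation when their event time is reached (mid-run track arrivals).
    Species counts are sampled whenever the clock passes a requested sample
    time; returns the count time series and the final state.  The returned
    series carries cumulative per-reaction event counts in
    ``df.attrs["event_counts"]``.

    ``engine="fast"`` runs the whole loop in a compiled kernel;
    ``engine="reference"`` uses the pure-Python sweep (the auditable
    implementation, also the one that fills ``event_log``).
    """
    report = validate_system(system, box.side_length)
    if not report.passed:
        raise ValueError("invalid system for this box: " + "; ".join(report.failures))
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    schedule = schedule or TimeStepSchedule()
    state = initial.copy()
    diffusion = system.diffusion_array()

    pending = sorted(injections or [], key=lambda item: item[0])
    for t_inj, _ in pending:
        if not (initial.time <= t_inj <= t_end):
            raise ValueError(f"injection time {t_inj} outside [{initial.time}, {t_end}]")
    if sample_times is None:
        sample_times = np.linspace(initial.time, t_end, 101)[1:]
    sample_times = np.asarray(sample_times, dtype=float)

    if engine == "fast":
        return _run_sbs_fast(
            state, system, box, t_end, rng, schedule, pending, sample_times
        )

    rows = []
    times = []
    isamp = 0
    event_log = event_log if event_log is not None else []

    def record_until(t_now: float) -> None:
        nonlocal isamp
        while isamp < len(sample_times) and sample_times[isamp] <= t_now:
            rows.append(state.counts(system.n_species))
            times.append(sample_times[isamp])
            isamp += 1

    while state.time < t_end - 1e-30:
        while pending and pending[0][0] <= state.time:
            _, delta = pending.pop(0)
            state = state.merge(delta)
            state = reaction_sweep(state, system, box, rng, event_log)
        dt = min(schedule.dt_at(state.time), t_end - state.time)
        if pending:
            dt = min(dt, max(pending[0][0] - state.time, 1e-30))
        diffusion_step(state, dt, rng, diffusion, box)
        state = reaction_sweep(state, system, box, rng, event_log)
        record_until(state.time)
    record_until(t_end)

    df = pd.DataFrame(np.array(rows, dtype=np.int64).reshape(-1, system.n_species),
                      columns=system.names)
    df.insert(0, "time_s", np.array(times))
    ev = {}
    for e in event_log:
        ev[e.reaction_id] = ev.get(e.reaction_id, 0) + 1
    df.attrs["event_counts"] = ev
    return df, state


def _reaction_tables(system: ChemicalSystem):
    """Flat lookup tables of the network for the compiled kernel."""
    n_s = system.n_species
    n_r = len(system.reactions)
    rlookup = np.full((n_s, n_s), -1, dtype=np.int64)
    radius = np.zeros(n_r)
    prods = np.full((n_r, 3), -1, dtype=np.int64)
    for m, r in enumerate(system.reactions):
        i, j = (system.index[n] for n in r.reactants)
        rlookup[i, j] = m
        rlookup[j, i] = m
        radius[m] = r.reaction_radius or 0.0
        for p, name in enumerate(r.products):
            prods[m, p] = system.index[name]
    return rlookup, radius, prods


def _run_sbs_fast(state, system, box, t_end, rng, schedule, pending, sample_times):
    from ._sbs_kernel import sbs_core

    n_inj_particles = sum(d.n for _, d in pending)
    cap = 2 * (state.n + n_inj_particles) + 64
    pos = np.zeros((cap, 3))
    sp = np.zeros(cap, dtype=np.int64)
    pos[: state.n] = state.positions
    sp[: state.n] = state.species

    inj_time = np.array([t for t, _ in pending])
    inj_ptr = np.zeros(len(pending) + 1, dtype=np.int64)
    for q, (_, d) in enumerate(pending):
        inj_ptr[q + 1] = inj_ptr[q] + d.n
    if pending:
        inj_pos = np.vstack([d.positions for _, d in pending])
        inj_sp = np.concatenate([d.species for _, d in pending])
    else:
        inj_pos = np.zeros((0, 3))
        inj_sp = np.zeros(0, dtype=np.int64)

    phases = np.array(schedule.phases)
    rlookup, radius, prods = _reaction_tables(system)
    counts = state.counts(system.n_species).astype(np.int64)
    seed = int(rng.integers(0, 2**31 - 1))
    out, n_live, event_counts = sbs_core(
        pos, sp, state.n, state.time, float(t_end),
        phases[:, 0].copy(), phases[:, 1].copy(), box.side_length,
        system.diffusion_array(), rlookup, radius, prods, counts,
        sample_times, inj_time, inj_ptr, inj_pos, inj_sp, seed, PRODUCT_JITTER,
    )
    df = pd.DataFrame(out, columns=system.names)
    df.insert(0, "time_s", sample_times)
    df.attrs["event_counts"] = {
        r.id: int(event_counts[m]) for m, r in enumerate(system.reactions)
    }
    final = ParticleState(pos[:n_live].copy(), sp[:n_live].copy(), float(t_end))
    return df, final


def uniform_state(
    counts: dict[str, int] | np.ndarray,
    system: ChemicalSystem,
    box: SimulationBox,
    rng: np.random.Generator,
    time: float = 0.0,
) -> ParticleState:
    """Well-mixed state: given counts placed uniformly in the box."""
    if isinstance(counts, dict):
        vec = np.zeros(system.n_species, dtype=np.int64)
        for name, n in counts.items():
            vec[system.index[name]] = n
    else:
        vec = np.asarray(counts, dtype=np.int64)
    species = np.repeat(np.arange(system.n_species), vec)
    L = box.side_length
    positions = rng.uniform(-0.5 * L, 0.5 * L, size=(len(species), 3))
    return ParticleState(positions, species, time)
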