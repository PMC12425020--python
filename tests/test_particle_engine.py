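"""Brownian-dynamics engine: wrapping, minimum image, diffusion, reactions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsechem import ParticleState, SimulationBox, minimum_image, wrap_position
from pulsechem.constants import N_AVOGADRO
from pulsechem.particle_engine import (
    TimeStepSchedule,
    brute_force_candidate_pairs,
    diffusion_step,
    reaction_sweep,
    run_sbs,
    uniform_state,
)


@pytest.mark.parametrize(
    "x,L,expected",
    [
        (0.5e-6, 1e-6, -0.5e-6),  # on the upper face: re-enter opposite side
        (0.3e-6, 1e-6, 0.3e-6),  # interior point unchanged
        (-0.7e-6, 1e-6, 0.3e-6),  # below the lower face
    ],
)
def test_wrap_position_examples(x, L, expected):
    assert wrap_position(x, L) == pytest.approx(expected)


@pytest.mark.parametrize(
    "dx,L,expected",
    [
        (0.9e-6, 1e-6, -0.1e-6),
        (0.2e-6, 1e-6, 0.2e-6),
        (-0.6e-6, 1e-6, 0.4e-6),
    ],
)
def test_minimum_image_examples(dx, L, expected):
    assert minimum_image(dx, L) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(
    x=st.floats(-1.5, 1.5, allow_nan=False),
    L=st.floats(0.1, 10.0),
)
def test_wrap_closure_and_min_image_bound(x, L):
    w = wrap_position(x, L)
    assert -L / 2 <= w < L / 2
    m = minimum_image(x, L)
    assert abs(m) <= L / 2 + 1e-12
    # wrapping is idempotent and the image differs by an integer number of L
    assert wrap_position(w, L) == pytest.approx(w)
    assert (x - w) / L == pytest.approx(round((x - w) / L), abs=1e-9)


def test_diffusion_step_sigma_and_sink(system, rng):
    box = SimulationBox(1e-6)
    st_ = uniform_state({"e_aq": 50000, "H2O": 1000}, system, box, rng)
    p0 = st_.positions.copy()
    D = system.diffusion_array()
    dt = 1e-12
    diffusion_step(st_, dt, rng, D, box)
    moved = st_.species == system.index["e_aq"]
    frozen = st_.species == system.index["H2O"]
    assert np.array_equal(st_.positions[frozen], p0[frozen])
    # per-axis std sqrt(2 D dt) ~ 9.90e-11 m for the hydrated electron
    disp = st_.positions[moved] - p0[moved]
    disp = minimum_image(disp, box.side_length)  # undo rare wraps
    sigma = np.sqrt(2 * 4.9e-9 * dt)
    assert sigma == pytest.approx(9.90e-11, rel=1e-2)
    assert disp.std() == pytest.approx(sigma, rel=0.02)
    # Einstein relation: 3D MSD = 6 D dt
    msd = (disp**2).sum(axis=1).mean()
    assert msd == pytest.approx(6 * 4.9e-9 * dt, rel=0.03)


def test_reaction_across_periodic_boundary(system, rng):
    """Reactants hugging opposite faces react through the boundary (PBC2)."""
    L = 8e-9
    box = SimulationBox(L)
    e = system.index["e_aq"]
    state = ParticleState(
        np.array([[-0.49 * L, 0, 0], [0.49 * L, 0, 0]]), np.array([e, e]), 0.0
    )
    # direct distance 0.98 L; minimum-image distance 0.02 L < R(R1)
    assert 0.02 * L < system.reaction("R1").reaction_radius
    log = []
    out = reaction_sweep(state, system, box, rng, event_log=log)
    counts = {n: int(c) for n, c in zip(system.names, out.counts(system.n_species))}
    assert [ev.reaction_id for ev in log] == ["R1"]
    assert counts["e_aq"] == 0 and counts["H2"] == 1 and counts["OH-"] == 2


def test_single_particle_never_reacts(system, rng):
    box = SimulationBox(1e-7)
    state = ParticleState(np.zeros((1, 3)), np.array([system.index["OH"]]), 0.0)
    out = reaction_sweep(state, system, box, rng)
    assert out.n == 1


def test_three_in_range_fire_exactly_once(system, rng):
    """Three mutually-in-range electrons: one pair reacts, one survives."""
    box = SimulationBox(1e-7)
    e = system.index["e_aq"]
    pos = np.array([[0, 0, 0], [1e-10, 0, 0], [0, 1e-10, 0]])
    out = reaction_sweep(ParticleState(pos, np.array([e, e, e]), 0.0), system, box, rng)
    counts = out.counts(system.n_species)
    assert counts[system.index["e_aq"]] == 1
    assert counts[system.index["H2"]] == 1
    assert counts[system.index["OH-"]] == 2


def test_cell_list_matches_brute_force(system, rng):
    """The k-d tree candidate search equals the O(n^2) oracle."""
    from pulsechem.particle_engine import _candidate_pairs

    box = SimulationBox(5e-8)
    for _ in range(20):
        pos = rng.uniform(-0.5, 0.5, size=(60, 3)) * box.side_length
        r = 4e-9
        a = {tuple(sorted(p)) for p in _candidate_pairs(pos, box, r)}
        b = {tuple(sorted(p)) for p in brute_force_candidate_pairs(pos, box, r)}
        assert a == b


def test_event_conservation(system, rng):
    """Each reaction event conserves charge and H/O atoms (implicit water
    included) and changes the particle count by the stoichiometry."""
    box = SimulationBox(2e-8)
    state = uniform_state({"e_aq": 40, "OH": 40, "H": 30, "H+": 30}, system, box, rng)
    charge = np.array([s.charge for s in system.species])
    nh = np.array([s.n_hydrogen for s in system.species])
    no = np.array([s.n_oxygen for s in system.species])
    log = []
    prev = state.counts(system.n_species)
    D = system.diffusion_array()
    for _ in range(300):
        diffusion_step(state, 1e-12, rng, D, box)
        state = reaction_sweep(state, system, box, rng, event_log=log)
    after = state.counts(system.n_species)
    assert len(log) > 0, "no reactions fired; conditions too dilute"
    dn = after - prev
    water = sum(system.reaction(ev.reaction_id).implicit_water for ev in log)
    assert charge @ dn == 0
    # water consumed from the bath (implicit_water < 0) surfaces as tracked H/O
    assert nh @ dn == -2 * water
    assert no @ dn == -1 * water
    expected_dn = np.zeros(system.n_species, dtype=int)
    for ev in log:
        r = system.reaction(ev.reaction_id)
        for name in r.reactants:
            expected_dn[system.index[name]] -= 1
        for name in r.products:
            expected_dn[system.index[name]] += 1
    assert np.array_equal(dn, expected_dn)


def test_positions_stay_in_box_through_run(system, rng):
    box = SimulationBox(3e-8)
    state = uniform_state({"e_aq": 50, "OH": 50}, system, box, rng)
    sched = TimeStepSchedule([(np.inf, 1e-11)])
    _, final = run_sbs(state, system, box, 5e-9, rng, schedule=sched)
    assert np.all(final.positions >= -box.side_length / 2)
    assert np.all(final.positions < box.side_length / 2)


def test_run_sbs_empty_state_is_flat(system, rng):
    box = SimulationBox(1e-7)
    df, final = run_sbs(ParticleState.empty(), system, box, 1e-9, rng,
                        schedule=TimeStepSchedule([(np.inf, 1e-11)]))
    assert final.n == 0
    assert (df[system.names].to_numpy() == 0).all()


def test_run_sbs_deterministic_under_seed(system):
    box = SimulationBox(4e-8)
    sched = TimeStepSchedule([(np.inf, 1e-12)])
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        state = uniform_state({"e_aq": 120, "OH": 120}, system, box, rng)
        df, final = run_sbs(state, system, box, 2e-10, rng, schedule=sched)
        outs.append((df[system.names].to_numpy(), final.positions))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.allclose(outs[0][1], outs[1][1])


def test_fast_and_reference_engines_agree_statistically(system):
    """Compiled kernel and pure-Python sweep give the same mean kinetics."""
    box = SimulationBox(5e-8)
    sched = TimeStepSchedule([(np.inf, 1e-12)])
    finals = {"fast": [], "reference": []}
    for engine in finals:
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            state = uniform_state({"e_aq": 150, "OH": 150}, system, box, rng)
            _, final = run_sbs(
                state, system, box, 3e-10, rng, schedule=sched, engine=engine
            )
            finals[engine].append(final.counts(system.n_species))
    a = np.mean(finals["fast"], axis=0)
    b = np.mean(finals["reference"], axis=0)
    e = system.index["e_aq"]
    # both should consume a similar number of electrons (Poisson-level agreement)
    consumed_a, consumed_b = 150 - a[e], 150 - b[e]
    assert consumed_a > 0 and consumed_b > 0
    assert abs(consumed_a - consumed_b) < 4 * np.sqrt(consumed_a + consumed_b)


def test_injection_outside_window_rejected(system, rng):
    box = SimulationBox(1e-7)
    delta = uniform_state({"OH": 5}, system, box, rng)
    with pytest.raises(ValueError, match="injection"):
        run_sbs(ParticleState.empty(), system, box, 1e-9, rng,
                injections=[(5e-9, delta)])
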