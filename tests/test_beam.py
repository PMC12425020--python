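"""Beam bookkeeping, fast mode, threshold finder, full pipeline."""

import numpy as np
import pytest

from pulsechem import (
    ConcentrationState,
    IrradiationConfig,
    PulseBeam,
    TrackModel,
    let_from_energy,
    n_primaries,
    pulse_schedule,
    run_fast_mode,
    run_irradiation,
)
from pulsechem.beam import (
    find_dav_threshold,
    injection_from_yields,
    order_of_magnitude,
    validation_mixture,
)
from pulsechem.constants import MOLAR_PER_GRAY_PER_G, N_AVOGADRO
from pulsechem.odes import integrate
from pulsechem.particle_engine import TimeStepSchedule


def test_n_primaries_dose_let_identity():
    """1 Gy in a 2 um box at 0.96 keV/um needs 26 primaries, and the
    inverse identity LET = D rho L^2 / N recovers the LET."""
    assert n_primaries(1.0, 2e-6, 0.96) == 26
    from pulsechem.constants import EV_IN_JOULE, WATER_DENSITY

    let_back = (
        1.0 * WATER_DENSITY * (2e-6) ** 2 / 26
    ) / (EV_IN_JOULE * 1e3 / 1e-6)  # J/m -> keV/um
    assert let_back == pytest.approx(0.96, rel=0.01)
    # linearity: doubling the dose doubles N within rounding
    assert abs(n_primaries(2.0, 2e-6, 0.96) - 52) <= 1


def test_n_primaries_zero_rounds_error():
    with pytest.raises(ValueError, match="fractionate"):
        n_primaries(1e-4, 2e-7, 10.0)


def test_let_interpolation_70mev():
    assert let_from_energy(70.0) == pytest.approx(0.96, abs=0.005)
    with pytest.raises(ValueError, match="outside"):
        let_from_energy(1e4)


def test_beam_derived_quantities():
    # 1e6 Gy/s * 1 us = 1 Gy per pulse; 100 Gy/s -> 100 Hz; 20 Gy -> 20 pulses
    beam = PulseBeam(1e-6, 1e6, 100.0, 20.0)
    assert beam.dose_per_pulse == pytest.approx(1.0)
    assert beam.frequency == pytest.approx(100.0)
    assert beam.period == pytest.approx(0.01)
    assert beam.n_pulses == 20


def test_overlapping_pulses_rejected():
    with pytest.raises(ValueError, match="overlap"):
        PulseBeam(1e-6, 1e6, 1.1e6, 20.0)


def test_pulse_schedule_windows(rng):
    beam = PulseBeam(1e-6, 1e6, 100.0, 20.0)
    sched = pulse_schedule(beam, 26, rng)
    assert len(sched) == 20
    assert sched[0][0] == 0.0
    # irradiation spans ~0.19 s (19 periods) plus the last pulse width
    assert sched[-1][0] == pytest.approx(0.19)
    for start, arrivals in sched:
        assert np.all(arrivals >= start)
        assert np.all(arrivals <= start + beam.fwhm)
        assert np.all(np.diff(arrivals) >= 0)


def test_injection_unit_conversion(system):
    """G = 2.6/100 eV at 1 Gy injects 2.6 * 0.10364 uM ~ 0.27 uM."""
    delta = injection_from_yields({"e_aq": 2.6}, 1.0, system)
    assert delta[system.index["e_aq"]] == pytest.approx(2.6 * 0.10364e-6, rel=1e-3)


def test_fast_mode_single_pulse_equals_plain_integration(system):
    beam = PulseBeam(1e-6, 1e6, 100.0, 1.0)  # a single pulse
    from pulsechem.chemistry import DEFAULT_ESCAPE_YIELDS

    series, report = run_fast_mode(beam, system, horizon=1.0)
    inj = injection_from_yields(DEFAULT_ESCAPE_YIELDS, 1.0, system)
    state = ConcentrationState(system.background_array() + inj, 0.0, 1.0)
    direct = integrate(state, system, 1.0, sample_times=np.array([1.0]))
    for name in system.names:
        assert report.final_concentrations[name] == pytest.approx(
            float(direct[name].iloc[-1]), rel=1e-6, abs=1e-18
        )


def test_gvalue_unit_identity(system):
    beam = PulseBeam(1e-6, 1e6, 100.0, 1.0)
    _, report = run_fast_mode(beam, system, horizon=1.0)
    for name in system.names:
        assert report.g_1e7_mol_per_j[name] == pytest.approx(
            report.g_per_100ev[name] * 1.0364, rel=1e-3, abs=1e-12
        )


def test_threshold_zero_injection_flagged(system):
    result = find_dav_threshold(
        1e6, system, np.zeros(system.n_species),
        dav_grid=np.logspace(0, 2, 5), total_dose=3.0,
    )
    assert result.flag == "never"
    assert result.threshold is None


def test_order_of_magnitude():
    assert order_of_magnitude(178.0) == 100.0
    assert order_of_magnitude(5.2) == 10.0
    assert order_of_magnitude(2.9) == 1.0


def test_threshold_monotone_in_pulse_dose_rate(system):
    """Threshold average dose rate grows with the pulse dose rate."""
    grid = np.logspace(-1, 4, 26)
    thr = []
    for dp_rate in (2e5, 1e6):
        res = find_dav_threshold(dp_rate, system, dav_grid=grid, total_dose=4.0)
        assert res.flag == "ok"
        thr.append(res.threshold)
    assert thr[1] > thr[0]


def test_particle_concentration_roundtrip(system, rng):
    """counts -> mol/L -> counts is exact for integer counts."""
    V = 1e-15
    n = rng.integers(0, 10000, system.n_species)
    c = n / (N_AVOGADRO * V)
    back = np.rint(c * N_AVOGADRO * V).astype(int)
    assert np.array_equal(back, n)


_DESK_SCHED = TimeStepSchedule(
    [(1e-9, 1e-12), (1e-8, 1e-11), (1e-7, 1e-10), (1e-6, 1e-9), (np.inf, 1e-8)]
)


def test_full_irradiation_single_pulse_behavior(system):
    """After one 1 Gy pulse and 10 s: molecular products persist, radicals
    are consumed to (near) zero."""
    config = IrradiationConfig(
        box_length=5e-7, let_kev_um=0.96, t_hom=5e-6, horizon=10.0,
        sbs_schedule=_DESK_SCHED,
    )
    beam = PulseBeam(1e-6, 1e6, 100.0, 1.0)
    rng = np.random.default_rng(3)
    series, report = run_irradiation(
        config, beam, system, TrackModel(let_kev_um=0.96), rng,
        dose_tolerance=0.5,
    )
    final = report.final_concentrations
    assert final["H2"] > 1e-8
    assert final["H2O2"] > 1e-8
    for radical in ("e_aq", "OH", "H"):
        assert final[radical] < 1e-10
    # G-values normalised to the booked dose are in the physical ballpark
    assert 0.1 < report.g_per_100ev["H2"] < 2.0
    assert 0.1 < report.g_per_100ev["H2O2"] < 2.0


def test_full_irradiation_dose_bookkeeping(system):
    config = IrradiationConfig(
        box_length=5e-7, let_kev_um=0.96, t_hom=2e-6, horizon=0.01,
        sbs_schedule=_DESK_SCHED,
    )
    beam = PulseBeam(1e-6, 1e6, 1000.0, 3.0)
    rng = np.random.default_rng(11)
    _, report = run_irradiation(
        config, beam, system, TrackModel(let_kev_um=0.96), rng, dose_tolerance=0.5
    )
    # booked dose equals N_tracks * LET * L / mass within straggling noise
    n = n_primaries(1.0, 5e-7, 0.96) * 3
    from pulsechem.constants import EV_IN_JOULE, WATER_DENSITY

    expected = n * 0.96e3 * EV_IN_JOULE * 0.5 / (WATER_DENSITY * (5e-7) ** 3)
    assert report.total_dose == pytest.approx(expected, rel=0.25)
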