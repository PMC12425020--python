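"""Deterministic rate-equation solver for the homogeneous stage.

Once the species are well mixed, the chemistry reduces to a stiff system of
ordinary differential equations.  Each reaction contributes a mass-action
rate term; self-reactions enter their own reactant's balance with
stoichiometric coefficient 2 and rate coefficient k = (tabulated 2k)/2, e.g.

    d[e_aq]/dt = -2 k1 [e_aq]^2 - k2 [e_aq][OH] - ...

Water re-dissociation (reverse of R9) is a constant source k9*Kw for H+ and
OH-, so neutral water is a fixed point of the system.

The network spans ~14 decades in time (ps-scale radical kinetics to the
10 s post-irradiation relaxation), hence the implicit (stiff) integrator
with an analytic Jacobian.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import ChemicalSystem
from .constants import K_W, LITRE_TO_M3
from .ssa import ConcentrationState, log_time_grid

__all__ = ["build_rhs", "build_jacobian", "integrate", "compare_trajectories"]

#: Default solver tolerances: relative 1e-8, absolute 1e-18 mol/L.
RTOL_DEFAULT = 1.0e-8
ATOL_DEFAULT = 1.0e-18


def _network_arrays(system: ChemicalSystem, water_source: bool):
    """Stoichiometry matrix, reactant index pairs and rate coefficients.

    Rates are returned in L mol^-1 s^-1 acting on mol/L concentrations;
    for self-reactions the coefficient is tabulated/2 and the reactant row
    of the stoichiometry matrix carries -2.
    """
    n_s = system.n_species
    n_r = len(system.reactions)
    S = np.zeros((n_s, n_r))
    ia = np.zeros(n_r, dtype=int)
    ib = np.zeros(n_r, dtype=int)
    k = np.zeros(n_r)
    for m, r in enumerate(system.reactions):
        k[m] = r.rate_coefficient / LITRE_TO_M3
        ia[m] = system.index[r.reactants[0]]
        ib[m] = system.index[r.reactants[1]]
        for name in r.reactants:
            S[system.index[name], m] -= 1
        for name in r.products:
            S[system.index[name], m] += 1
    source = np.zeros(n_s)
    if water_source and "R9" in {r.id for r in system.reactions}:
        k9 = system.reaction("R9").tabulated_rate / LITRE_TO_M3
        source[system.index["H+"]] += k9 * K_W
        source[system.index["OH-"]] += k9 * K_W
    return S, ia, ib, k, source


def build_rhs(system: ChemicalSystem, water_source: bool = True):
    """Right-hand side C -> dC/dt (mol/L/s) of the rate equations."""
    S, ia, ib, k, source = _network_arrays(system, water_source)

    def rhs(t, c):
        rates = k * c[ia] * c[ib]
        return S @ rates + source

    return rhs


def build_jacobian(system: ChemicalSystem, water_source: bool = True):
    """Analytic Jacobian d(dC/dt)/dC of the rate equations."""
    S, ia, ib, k, _ = _network_arrays(system, water_source)
    n_s = system.n_species

    def jac(t, c):
        J = np.zeros((n_s, n_s))
        for m in range(len(k)):
            a, b = ia[m], ib[m]
            col = S[:, m] * k[m]
            J[:, a] += col * c[b]
            J[:, b] += col * c[a]
        return J

    return jac


def integrate(
    initial: ConcentrationState,
    system: ChemicalSystem,
    t_end: float,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    sample_times: np.ndarray | None = None,
    water_source: bool = True,
    track_production: bool = False,
    method: str = "LSODA",
) -> pd.DataFrame:
    """Integrate the network from ``initial.time`` to ``t_end``.

    Returns the trajectory on a log-time grid (or the given sample times).
    With ``track_production`` the gross production of every species (the
    positive stoichiometric contributions only) is accumulated in parallel
    columns ``prod_<name>``, which is what cumulative yields are read from.
    """
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    if sample_times is None:
        t0 = max(initial.time, (t_end - initial.time) * 1e-9 + initial.time)
        if initial.time == 0.0:
            sample_times = log_time_grid(t_end * 1e-9, t_end)
        else:
            sample_times = np.linspace(initial.time, t_end, 256)[1:]
    sample_times = np.asarray(sample_times, dtype=float)

    S, ia, ib, k, source = _network_arrays(system, water_source)
    n_s = system.n_species
    S_pos = np.where(S > 0, S, 0.0)

    if track_production:
        def rhs(t, y):
            c = y[:n_s]
            rates = k * c[ia] * c[ib]
            return np.concatenate([S @ rates + source, S_pos @ rates])

        def jac(t, y):
            c = y[:n_s]
            J = np.zeros((2 * n_s, 2 * n_s))
            for m in range(len(k)):
                a, b = ia[m], ib[m]
                col = S[:, m] * k[m]
                colp = S_pos[:, m] * k[m]
                J[:n_s, a] += col * c[b]
                J[:n_s, b] += col * c[a]
                J[n_s:, a] += colp * c[b]
                J[n_s:, b] += colp * c[a]
            return J

        y0 = np.concatenate([initial.concentrations, np.zeros(n_s)])
    else:
        def rhs(t, y):
            rates = k * y[ia] * y[ib]
            return S @ rates + source

        def jac(t, y):
            J = np.zeros((n_s, n_s))
            for m in range(len(k)):
                a, b = ia[m], ib[m]
                col = S[:, m] * k[m]
                J[:, a] += col * y[b]
                J[:, b] += col * y[a]
            return J

        y0 = initial.concentrations.copy()

    sol = solve_ivp(
        rhs,
        (initial.time, t_end),
        y0,
        method=method,
        jac=jac,
        rtol=rtol,
        atol=atol,
        t_eval=sample_times,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y.T
    if np.any(y[:, :n_s] < -atol * 100):
        warnings.warn("integrator undershoot below -tolerance; clipping to 0")
    y = np.clip(y, 0.0, None)
    cols = list(system.names)
    if track_production:
        cols += [f"prod_{n}" for n in system.names]
    df = pd.DataFrame(y, columns=cols)
    df.insert(0, "time_s", sol.t)
    return df


def compare_trajectories(
    a: pd.DataFrame,
    b: pd.DataFrame,
    species: list[str] | None = None,
    floor: float = 1.0e-12,
) -> float:
    """Max per-species ratio deviation |a/b - 1| * 100 (%) on a common grid.

    Series are interpolated log-linearly in time onto the overlap of the two
    grids; times where both series are below ``floor`` (mol/L) are excluded
    to avoid 0/0 comparisons of empty species.
    """
    if species is None:
        species = [c for c in a.columns if c != "time_s" and c in b.columns]
    ta, tb = a["time_s"].to_numpy(), b["time_s"].to_numpy()
    lo, hi = max(ta.min(), tb.min()), min(ta.max(), tb.max())
    if lo >= hi:
        raise ValueError("disjoint time ranges")
    grid = np.logspace(np.log10(lo), np.log10(hi), 200) if lo > 0 else np.linspace(lo, hi, 200)
    worst = 0.0
    for name in species:
        va = np.interp(np.log(grid), np.log(ta), a[name].to_numpy())
        vb = np.interp(np.log(grid), np.log(tb), b[name].to_numpy())
        mask = (np.abs(va) >= floor) | (np.abs(vb) >= floor)
        if not mask.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs(va[mask] / vb[mask] - 1.0) * 100.0
        worst = max(worst, float(np.max(dev)))
    return worst
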