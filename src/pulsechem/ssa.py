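"""Gillespie direct-method stochastic solver for well-mixed kinetics.

Serves as the stochastic reference for the deterministic ODE solver and the
particle engine.  Propensities follow the mass-action convention consistent
with the table rates: for a hetero reaction A + B the propensity is
k n_A n_B / (N_A V); for a self reaction 2A with tabulated rate 2k it is
(2k) n_A (n_A - 1) / (2 N_A V), whose deterministic limit is the rate law
d[A]/dt = -(2k)[A]^2.

Water re-dissociation (the reverse of R9) enters as a zeroth-order source
with propensity k9 * Kw * N_A * V producing one H+ and one OH-, making
neutral water ([H+] = [OH-] = 1e-7 M) a stochastic fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .chemistry import ChemicalSystem
from .constants import K_W, LITRE_TO_M3, N_AVOGADRO

__all__ = [
    "ConcentrationState",
    "propensity",
    "run_ssa",
    "ssa_mean",
    "log_time_grid",
]


@dataclass
class ConcentrationState:
    """Per-species molar concentrations with the volume used for counts."""

    concentrations: np.ndarray  # mol/L, aligned with system.names
    time: float = 0.0  # s
    volume: float = 1.0e-15  # L

    def copy(self) -> "ConcentrationState":
        return ConcentrationState(self.concentrations.copy(), self.time, self.volume)

    def counts(self) -> np.ndarray:
        """Integer molecule counts n = C * N_A * V (rounded)."""
        n = np.rint(self.concentrations * N_AVOGADRO * self.volume)
        if np.any(n < 0):
            raise ValueError("negative concentration")
        return n.astype(np.int64)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, volume: float, time: float = 0.0
    ) -> "ConcentrationState":
        conc = np.asarray(counts, dtype=float) / (N_AVOGADRO * volume)
        return cls(conc, time, volume)


def log_time_grid(t_start: float, t_end: float, points_per_decade: int = 64) -> np.ndarray:
    """Log-spaced sampling grid, 64 points per decade by default."""
    if not 0 < t_start < t_end:
        raise ValueError("need 0 < t_start < t_end")
    n_dec = np.log10(t_end / t_start)
    n = max(2, int(np.ceil(n_dec * points_per_decade)) + 1)
    return np.logspace(np.log10(t_start), np.log10(t_end), n)


def _rate_litre(reaction) -> float:
    """Tabulated rate back in L mol^-1 s^-1 for count-based propensities."""
    return reaction.tabulated_rate / LITRE_TO_M3


def propensity(reaction, counts: np.ndarray, volume: float, system: ChemicalSystem) -> float:
    """Stochastic propensity (events/s) of one reaction at given counts."""
    k = _rate_litre(reaction)
    nav = N_AVOGADRO * volume
    i = system.index[reaction.reactants[0]]
    if reaction.is_self:
        n = counts[i]
        return k * n * (n - 1) / (2.0 * nav)
    j = system.index[reaction.reactants[1]]
    return k * counts[i] * counts[j] / nav


def _compile_tables(system: ChemicalSystem, volume: float, water_source: bool):
    """Pack the network into flat arrays for the jitted core."""
    n_r = len(system.reactions) + (1 if water_source else 0)
    r1 = np.full(n_r, -1, dtype=np.int64)
    r2 = np.full(n_r, -1, dtype=np.int64)
    self_flag = np.zeros(n_r, dtype=np.bool_)
    coef = np.zeros(n_r)
    prods = np.full((n_r, 3), -1, dtype=np.int64)
    nav = N_AVOGADRO * volume
    for m, r in enumerate(system.reactions):
        k = _rate_litre(r)
        r1[m] = system.index[r.reactants[0]]
        r2[m] = system.index[r.reactants[1]]
        if r.is_self:
            self_flag[m] = True
            coef[m] = k / (2.0 * nav)
        else:
            coef[m] = k / nav
        for p, name in enumerate(r.products):
            prods[m, p] = system.index[name]
    if water_source:
        m = n_r - 1
        try:
            k9 = _rate_litre(system.reaction("R9"))
        except KeyError:
            k9 = 0.0
        coef[m] = k9 * K_W * nav  # events/s, zeroth order
        prods[m, 0] = system.index["H+"]
        prods[m, 1] = system.index["OH-"]
    return r1, r2, self_flag, coef, prods


@njit(cache=True)
def _ssa_core(n0, t0, t_end, r1, r2, self_flag, coef, prods, sample_t, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_species = n0.shape[0]
    n_r = coef.shape[0]
    n_samp = sample_t.shape[0]
    out = np.zeros((n_samp, n_species))
    n = n0.copy().astype(np.float64)
    a = np.zeros(n_r)
    t = t0
    isamp = 0
    while True:
        a_tot = 0.0
        for m in range(n_r):
            i = r1[m]
            if i < 0:
                a[m] = coef[m]
            elif self_flag[m]:
                a[m] = coef[m] * n[i] * (n[i] - 1.0)
            else:
                a[m] = coef[m] * n[i] * n[r2[m]]
            if a[m] < 0.0:
                a[m] = 0.0
            a_tot += a[m]
        if a_tot <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t + np.random.exponential(1.0 / a_tot)
        # flush samples up to the jump time (state is constant in between)
        while isamp < n_samp and sample_t[isamp] < t_next:
            for s in range(n_species):
                out[isamp, s] = n[s]
            isamp += 1
        if t_next > t_end or a_tot <= 0.0:
            break
        t = t_next
        # choose reaction proportional to propensity
        u = np.random.random() * a_tot
        m = 0
        acc = a[0]
        while acc < u and m < n_r - 1:
            m += 1
            acc += a[m]
        i = r1[m]
        if i >= 0:
            n[i] -= 1.0
            n[r2[m]] -= 1.0
        for p in range(3):
            j = prods[m, p]
            if j >= 0:
                n[j] += 1.0
    # pad trailing samples with the final state
    while isamp < n_samp:
        for s in range(n_species):
            out[isamp, s] = n[s]
        isamp += 1
    return out


def run_ssa(
    initial: ConcentrationState,
    system: ChemicalSystem,
    t_end: float,
    rng: np.random.Generator,
    sample_times: np.ndarray | None = None,
    water_source: bool = True,
) -> pd.DataFrame:
    """One exact direct-method trajectory, sampled on a log-time grid.

    Returns a DataFrame with a ``time_s`` column and one concentration
    column (mol/L) per species.
    """
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    if sample_times is None:
        t0 = max(initial.time, t_end * 1e-6)
        sample_times = log_time_grid(t0, t_end)
    sample_times = np.asarray(sample_times, dtype=float)
    tables = _compile_tables(system, initial.volume, water_source)
    seed = int(rng.integers(0, 2**31 - 1))
    counts = _ssa_core(
        initial.counts(), initial.time, float(t_end), *tables, sample_times, seed
    )
    conc = counts / (N_AVOGADRO * initial.volume)
    df = pd.DataFrame(conc, columns=system.names)
    df.insert(0, "time_s", sample_times)
    return df


def ssa_mean(
    initial: ConcentrationState,
    system: ChemicalSystem,
    t_end: float,
    rng: np.random.Generator,
    n_replicates: int = 100,
    sample_times: np.ndarray | None = None,
    water_source: bool = True,
) -> pd.DataFrame:
    """Mean concentration trajectory over seeded replicates."""
    if sample_times is None:
        t0 = max(initial.time, t_end * 1e-6)
        sample_times = log_time_grid(t0, t_end)
    acc = None
    for _ in range(n_replicates):
        df = run_ssa(initial, system, t_end, rng, sample_times, water_source)
        vals = df[system.names].to_numpy()
        acc = vals if acc is None else acc + vals
    mean = acc / n_replicates
    out = pd.DataFrame(mean, columns=system.names)
    out.insert(0, "time_s", np.asarray(sample_times, dtype=float))
    return out
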