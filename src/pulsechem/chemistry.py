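"""Reaction network for the radiolysis of pure water.

The network couples the seven tracked radiolytic species (hydrated electron,
hydroxyl radical, hydrogen atom, molecular hydrogen, hydrogen peroxide, and
the water ions) through nine diffusion-controlled reactions.  Rate constants
follow the convention of the radiolysis literature: for self-recombination
reactions (R1, R6, R8) the tabulated number is 2k, i.e. twice the rate
coefficient that multiplies [A]^2 in the empirical rate law.

Reaction radii are derived from the Smoluchowski relation for fully
diffusion-controlled reactions,

    k = 4 pi (D_A + D_B) N_A * R,

with the tabulated 2k used as the input rate for self-reactions (the factor
of two that appears when equating Fick's first law with the rate equation
for identical reactants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .constants import LITRE_TO_M3, N_AVOGADRO

__all__ = [
    "Species",
    "Reaction",
    "ChemicalSystem",
    "build_default_system",
    "reaction_radius",
    "validate_system",
    "DEFAULT_DIFFUSION",
    "DEFAULT_ESCAPE_YIELDS",
]


#: Default species diffusion coefficients (m^2/s) in liquid water at 25 C.
#: Literature-standard values; configurable through the species block of the
#: config file.  The water sink is inert and immobile.
DEFAULT_DIFFUSION = {
    "e_aq": 4.9e-9,
    "OH": 2.8e-9,
    "H": 7.0e-9,
    "H2": 4.8e-9,
    "H2O2": 2.3e-9,
    "H+": 9.46e-9,
    "OH-": 5.3e-9,
    "H2O": 0.0,
}

#: Default escape yields (species per 100 eV) of a low-LET track at ~1 us,
#: used to size per-pulse injections for the concentration-based solvers.
#: Literature-standard low-LET set; charge balances: 3.24 = 2.56 + 0.68.
DEFAULT_ESCAPE_YIELDS = {
    "e_aq": 2.56,
    "OH": 2.50,
    "H": 0.66,
    "H2": 0.45,
    "H2O2": 0.70,
    "H+": 3.24,
    "OH-": 0.68,
}

# Elemental composition (H, O) and charge per species, used for the
# conservation checks.
_COMPOSITION = {
    "e_aq": (0, 0, -1),
    "OH": (1, 1, 0),
    "H": (1, 0, 0),
    "H2": (2, 0, 0),
    "H2O2": (2, 2, 0),
    "H+": (1, 0, +1),
    "OH-": (1, 1, -1),
    "H2O": (2, 1, 0),
}


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by the simulation."""

    name: str
    diffusion_coefficient: float  # m^2/s
    background_concentration: float = 0.0  # mol/L, concentration solvers only
    n_hydrogen: int = 0
    n_oxygen: int = 0
    charge: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError(f"negative diffusion coefficient for {self.name}")


@dataclass
class Reaction:
    """A bimolecular reaction of the network.

    ``tabulated_rate`` is stored in m^3 mol^-1 s^-1 and carries the table
    convention: for ``is_self`` reactions it equals 2k.  ``implicit_water``
    is the signed count of bath water molecules consumed (negative) or
    produced (positive) to balance atoms; produced water that is tracked
    explicitly as the sink species needs no implicit entry.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    tabulated_rate: float  # m^3 mol^-1 s^-1, table convention (2k if self)
    is_self: bool = False
    implicit_water: int = 0
    reaction_radius: float | None = None  # m, derived

    @property
    def rate_coefficient(self) -> float:
        """Rate coefficient k of the rate law term k[A][B] (or k[A]^2)."""
        return self.tabulated_rate / 2.0 if self.is_self else self.tabulated_rate


class ChemicalSystem:
    """Species list plus reaction list with pairwise lookup indexes."""

    def __init__(self, species: list[Species], reactions: list[Reaction]):
        self.species = list(species)
        self.reactions = list(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self.index = {name: i for i, name in enumerate(names)}
        for r in self.reactions:
            for name in (*r.reactants, *r.products):
                if name not in self.index:
                    raise ValueError(f"{r.id}: unregistered species {name!r}")
        self._by_id = {r.id: r for r in self.reactions}
        # unordered reactant-pair -> reactions
        self.pair_index: dict[tuple[int, int], list[Reaction]] = {}
        for r in self.reactions:
            if len(r.reactants) == 2:
                i, j = sorted(self.index[n] for n in r.reactants)
                self.pair_index.setdefault((i, j), []).append(r)

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def reaction(self, rid: str) -> Reaction:
        return self._by_id[rid]

    def get_species(self, name: str) -> Species:
        return self.species[self.index[name]]

    def diffusion_array(self):
        import numpy as np

        return np.array([s.diffusion_coefficient for s in self.species])

    def background_array(self):
        import numpy as np

        return np.array([s.background_concentration for s in self.species])

    def subsystem(self, reaction_ids: list[str]) -> "ChemicalSystem":
        """A copy restricted to the given reactions (all species kept)."""
        reactions = [replace(self._by_id[rid]) for rid in reaction_ids]
        return ChemicalSystem(self.species, reactions)

    # -- balance bookkeeping --------------------------------------------
    def reaction_balance(self, r: Reaction) -> tuple[int, int, int]:
        """(dH, dO, dcharge) across the reaction, implicit water included.

        All three must be zero for a well-formed reaction.
        """
        dh = do = dq = 0
        for name in r.reactants:
            h, o, q = _COMPOSITION.get(name, (0, 0, 0))
            dh -= h
            do -= o
            dq -= q
        for name in r.products:
            h, o, q = _COMPOSITION.get(name, (0, 0, 0))
            dh += h
            do += o
            dq += q
        dh += 2 * r.implicit_water
        do += 1 * r.implicit_water
        return dh, do, dq


def reaction_radius(reaction: Reaction, species_table: dict[str, Species]) -> float:
    """Smoluchowski reaction radius (m) for a diffusion-controlled reaction.

    R = k_input / (4 pi (D_A + D_B) N_A), with k_input the tabulated rate
    (which is 2k for self-reactions) in m^3 mol^-1 s^-1.
    """
    if len(reaction.reactants) != 2:
        raise ValueError(f"{reaction.id}: reaction radius needs two reactants")
    d_total = sum(species_table[n].diffusion_coefficient for n in reaction.reactants)
    if reaction.tabulated_rate == 0.0:
        return 0.0
    if d_total <= 0.0:
        raise ValueError(
            f"{reaction.id}: zero total diffusion coefficient with nonzero rate"
        )
    return reaction.tabulated_rate / (4.0 * math.pi * d_total * N_AVOGADRO)


def _make_species(overrides: dict | None = None) -> list[Species]:
    diffusion = dict(DEFAULT_DIFFUSION)
    if overrides:
        diffusion.update(overrides)
    species = []
    for name, d in diffusion.items():
        h, o, q = _COMPOSITION[name]
        background = 1.0e-7 if name in ("H+", "OH-") else 0.0
        species.append(
            Species(
                name=name,
                diffusion_coefficient=d,
                background_concentration=background,
                n_hydrogen=h,
                n_oxygen=o,
                charge=q,
            )
        )
    return species


# (id, reactants, products, rate / 1e10 L/mol/s, is_self, implicit_water)
_TABLE = [
    ("R1", ("e_aq", "e_aq"), ("H2", "OH-", "OH-"), 1.3, True, -2),
    ("R2", ("e_aq", "OH"), ("OH-",), 3.0, False, 0),
    ("R3", ("e_aq", "H"), ("H2", "OH-"), 2.6, False, -1),
    ("R4", ("e_aq", "H+"), ("H",), 2.3, False, 0),
    ("R5", ("e_aq", "H2O2"), ("OH", "OH-"), 1.4, False, 0),
    ("R6", ("OH", "OH"), ("H2O2",), 0.95, True, 0),
    ("R7", ("OH", "H"), ("H2O",), 1.5, False, 0),
    ("R8", ("H", "H"), ("H2",), 1.1, True, 0),
    ("R9", ("H+", "OH-"), ("H2O",), 11.0, False, 0),
]


def build_default_system(diffusion_overrides: dict | None = None) -> ChemicalSystem:
    """The nine-reaction pure-water network with derived reaction radii.

    Rates are the standard tabulated values in units of 1e10 L mol^-1 s^-1
    (for R1, R6, R8 the tabulated number is 2k).  The reverse of R9 (water
    re-dissociation, H2O -> H+ + OH-) is not a listed reaction; the
    concentration solvers add it as a constant source k9*Kw so that neutral
    water is a fixed point.
    """
    species = _make_species(diffusion_overrides)
    table = {s.name: s for s in species}
    reactions = []
    for rid, reactants, products, rate_e10, is_self, water in _TABLE:
        r = Reaction(
            id=rid,
            reactants=reactants,
            products=products,
            tabulated_rate=rate_e10 * 1.0e10 * LITRE_TO_M3,
            is_self=is_self,
            implicit_water=water,
        )
        r.reaction_radius = reaction_radius(r, table)
        reactions.append(r)
    return ChemicalSystem(species, reactions)


@dataclass
class ValidationReport:
    """Outcome of the pre-run sanity checks of a chemical system."""

    checks: dict[str, bool] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


def validate_system(system: ChemicalSystem, L: float | None = None) -> ValidationReport:
    """Assert balance invariants and, if a box size is given, 2R < L.

    The minimum-image convention requires twice the reaction radius to be
    smaller than the box side, otherwise a reactant could react with its own
    periodic image.
    """
    report = ValidationReport()
    for r in system.reactions:
        dh, do, dq = system.reaction_balance(r)
        ok = dh == 0 and do == 0 and dq == 0
        report.checks[f"{r.id}:balance"] = ok
        if not ok:
            report.failures.append(
                f"{r.id}: unbalanced (dH={dh}, dO={do}, dcharge={dq})"
            )
        if L is not None:
            radius = r.reaction_radius
            if radius is None:
                radius = reaction_radius(r, {s.name: s for s in system.species})
            ok = 2.0 * radius < L
            report.checks[f"{r.id}:minimum_image"] = ok
            if not ok:
                report.failures.append(
                    f"{r.id}: 2R = {2 * radius:.3e} m not < L = {L:.3e} m"
                )
    return report
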