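"""Physical constants and unit conversions used across the package.

Internal unit conventions:

* lengths in metres, times in seconds,
* bimolecular rate constants stored in m^3 mol^-1 s^-1 (the conventional
  tabulated unit, L mol^-1 s^-1, is converted on input: 1 L = 1e-3 m^3),
* concentrations in mol/L at the API surface.
"""

#: Avogadro constant (mol^-1), CODATA exact.
N_AVOGADRO = 6.02214076e23

#: Elementary charge / 1 eV in joule, CODATA exact.
EV_IN_JOULE = 1.602176634e-19

#: Density of liquid water (kg/m^3) assumed throughout.
WATER_DENSITY = 1000.0

#: Ionic product of water at 25 C (mol^2/L^2); sets the H+/OH- equilibrium
#: concentration of 1e-7 mol/L in neutral water.
K_W = 1.0e-14

#: One chemical species per 100 eV of absorbed energy, expressed in mol/J.
#: 1/(100 eV * N_A) = 1.0364e-7 mol/J, the usual G-value conversion factor.
G_UNIT_MOL_PER_J = 1.0 / (100.0 * EV_IN_JOULE * N_AVOGADRO)

#: Molar concentration increment (mol/L) per gray per unit G-value
#: (species/100 eV) in liquid water: G_UNIT_MOL_PER_J * rho with rho = 1 kg/L.
MOLAR_PER_GRAY_PER_G = G_UNIT_MOL_PER_J * 1.0

#: Conversion from L mol^-1 s^-1 to the internal m^3 mol^-1 s^-1.
LITRE_TO_M3 = 1.0e-3
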