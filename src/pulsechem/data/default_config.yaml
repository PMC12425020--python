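# Default pulsed-irradiation setup: 70 MeV protons, 2 um box, 1 us pulses.
system:
  species:
    - {name: e_aq,  diffusion_coefficient: 4.9e-9,  background_concentration: 0.0}
    - {name: OH,    diffusion_coefficient: 2.8e-9,  background_concentration: 0.0}
    - {name: H,     diffusion_coefficient: 7.0e-9,  background_concentration: 0.0}
    - {name: H2,    diffusion_coefficient: 4.8e-9,  background_concentration: 0.0}
    - {name: H2O2,  diffusion_coefficient: 2.3e-9,  background_concentration: 0.0}
    - {name: H+,    diffusion_coefficient: 9.46e-9, background_concentration: 1.0e-7}
    - {name: OH-,   diffusion_coefficient: 5.3e-9,  background_concentration: 1.0e-7}
    - {name: H2O,   diffusion_coefficient: 0.0,     background_concentration: 0.0}
  reactions:
    # rate in 1e10 L/mol/s, table convention (self reactions list 2k)
    - {id: R1, reactants: [e_aq, e_aq], products: [H2, OH-, OH-], rate: 1.3,  self: true,  implicit_water: -2}
    - {id: R2, reactants: [e_aq, OH],   products: [OH-],          rate: 3.0,  self: false, implicit_water: 0}
    - {id: R3, reactants: [e_aq, H],    products: [H2, OH-],      rate: 2.6,  self: false, implicit_water: -1}
    - {id: R4, reactants: [e_aq, H+],   products: [H],            rate: 2.3,  self: false, implicit_water: 0}
    - {id: R5, reactants: [e_aq, H2O2], products: [OH, OH-],      rate: 1.4,  self: false, implicit_water: 0}
    - {id: R6, reactants: [OH, OH],     products: [H2O2],         rate: 0.95, self: true,  implicit_water: 0}
    - {id: R7, reactants: [OH, H],      products: [H2O],          rate: 1.5,  self: false, implicit_water: 0}
    - {id: R8, reactants: [H, H],       products: [H2],           rate: 1.1,  self: true,  implicit_water: 0}
    - {id: R9, reactants: [H+, OH-],    products: [H2O],          rate: 11.0, self: false, implicit_water: 0}

box:
  side_length: 2.0e-6      # m

beam:
  fwhm: 1.0e-6             # s
  pulse_dose_rate: 1.0e6   # Gy/s
  average_dose_rate: 100.0 # Gy/s
  total_dose: 20.0         # Gy

irradiation:
  energy_mev: 70.0         # proton kinetic energy; LET interpolated from the
                           # bundled stopping-power table unless let_kev_um set
  t_hom: 1.0e-5            # s, SBS -> ODE handoff after pulse end
  horizon: 10.0            # s, post-irradiation relaxation

track:
  radial_spread: 4.0e-9    # m
  cluster_mean_energy: 40.0  # eV
  handoff_yields:          # species per 100 eV at chemical-stage handoff
    e_aq: 4.6
    OH: 5.1
    H: 0.62
    H2: 0.15
    H+: 4.6

# escape yields at ~1 us used by the concentration-only fast mode
escape_yields:
  e_aq: 2.56
  OH: 2.50
  H: 0.66
  H2: 0.45
  H2O2: 0.70
  H+: 3.24
  OH-: 0.68
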