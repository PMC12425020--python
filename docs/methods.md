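# Methods

## Model overview

`pulsechem` simulates the chemical stage of water radiolysis under a
pulsed beam. Each pulse deposits dose Dp = D̊p·FWHM through a cubic box of
side L treated, via periodic boundary conditions, as one voxel of bulk
water. While the beam is on (and for a homogenisation time t_hom after
it), species are individual particles undergoing Brownian jumps and
distance-triggered reactions — the *non-homogeneous* stage, where the
clustered track structure matters. Between pulses and for 10 s after the
last one the species are well mixed and the system is advanced by
deterministic mass-action rate equations — the *homogeneous* stage. A
Gillespie stochastic sampler provides an independent reference for the
homogeneous stage. Post-irradiation yields are reported as G-values,
normalised to the booked energy (1 species/100 eV = 1.0364·10⁻⁷ mol/J).

## Reaction network

Nine diffusion-controlled reactions among e⁻aq, •OH, H•, H₂, H₂O₂, H⁺ and
OH⁻, with rate constants in the standard table convention: the number
listed for a self-reaction (e⁻aq+e⁻aq, •OH+•OH, H•+H•) is 2k, twice the
coefficient of [A]² in the rate law. Reaction radii follow Smoluchowski,
𝓡 = k_in/(4π(𝓓_A+𝓓_B)N_A), with k_in the tabulated value — hence 2k for
self-reactions, the factor that arises when Fick's first law is equated
with the empirical rate expression for identical reactants.

Water handling: water consumed by a reaction (e.g. 2e⁻aq + 2H₂O →
H₂ + 2OH⁻) is an implicit, unlimited bath and is recorded as a signed
stoichiometric count for the conservation checks; water *produced*
(•OH+H•, H⁺+OH⁻) is booked into an explicit immobile sink species so that
per-event particle bookkeeping is exact. The reverse of the ion
recombination (water re-dissociation) is modelled in the concentration
solvers as a constant source k₉·K_w (K_w = 10⁻¹⁴ mol²/L²) feeding H⁺ and
OH⁻, which makes neutral water ([H⁺]=[OH⁻]=10⁻⁷ M) an exact fixed point.
The particle engine omits this reverse channel: in a micrometre box the
neutral-water background amounts to far less than one ion pair, and
re-dissociation events are negligible on the simulated timescales. This
is a documented asymmetry between the particle and concentration
descriptions.

Diffusion coefficients are configurable per species; the defaults are
standard literature values for ambient liquid water (e⁻aq 4.9·10⁻⁹,
•OH 2.8·10⁻⁹, H• 7.0·10⁻⁹, H₂ 4.8·10⁻⁹, H₂O₂ 2.3·10⁻⁹, H⁺ 9.46·10⁻⁹,
OH⁻ 5.3·10⁻⁹ m²/s). All derived radii inherit this provenance; absolute
particle-stage kinetics shift if a different set is configured.

## Particle engine

Positions live in [−L/2, L/2)³. Each step draws isotropic Gaussian jumps
with per-axis σ = √(2𝓓dt), wraps coordinates periodically (PBC1), and
then fires every reactant pair whose *minimum-image* distance (PBC2) is
within the reaction radius. The minimum-image convention requires
2𝓡 < L, enforced at run setup. Pair resolution is greedy nearest-first
with random tie-breaks, so each particle reacts at most once per sweep;
products are placed at the diffusion-weighted midpoint (weights ∝ √𝓓 of
the partner, putting products nearer the slower reactant) with a 0.1 nm
jitter when a reaction has several products. Neighbor search uses a
periodic linked-cell grid inside a compiled (numba) kernel; a pure-Python
sweep with a periodic k-d tree and a brute-force O(n²) pairing serve as
behavioural oracles in the tests.

The time step follows a piecewise-constant log-graded schedule
(defaults: 0.1 ps below 1 ns, rising a decade per decade of elapsed time,
capped at 0.1 µs). Reactions are tested against static post-jump
positions, with no bridge-crossing correction. This plain scheme
reproduces the Smoluchowski rate only while the relative jump size is
small compared to the reaction radius: measured on the pure
self-recombination of e⁻aq (𝓡 = 0.175 nm), the effective rate is ~55% of
nominal at σ/𝓡 = 0.8 (1 ps steps) and converges to ~92% at σ/𝓡 = 0.25.
For the largest radius in the network (H⁺+OH⁻, 𝓡 = 0.985 nm; σ/𝓡 = 0.17
at 1 ps) the hyperbolic closed-form decay is reproduced to a few percent.
This dt-dependence is an inherent property of the step-by-step method;
it cancels in comparisons that share a schedule (e.g. the finite-size
suite) and is why quantitative single-reaction checks use the
diffusion-resolved ion pair.

## Well-mixed solvers

*Rate equations.* Each reaction contributes a mass-action term;
self-reactions enter their reactant's balance with coefficient 2 and
rate k = (2k)/2. Integration uses a stiff implicit method (LSODA; BDF
available) with an analytic Jacobian, rtol 10⁻⁸ and atol 10⁻¹⁸ mol/L —
the network spans ~14 decades of time, from sub-µs radical kinetics to
the 10 s relaxation. Trajectories are clipped at zero with a warning if
the solver undershoots beyond tolerance. An optional set of companion
states integrates gross production per species (positive stoichiometric
flux only), from which cumulative yields are read.

*Gillespie sampler.* Direct method with count-based propensities
(hetero: k·n_A·n_B/(N_A V); self with tabulated 2k:
(2k)·n_A(n_A−1)/(2N_A V)); the water source enters as a zeroth-order
channel with propensity k₉·K_w·N_A·V. The sampler is exact; its compiled
inner loop handles the ~10⁷ events per replicate of the validation
mixture in about a second.

*Cross-validation conditions.* The default validation mixture is the
escape-yield composition of one 1 Gy pulse (e⁻aq 2.56, •OH 2.50, H• 0.66,
H₂ 0.45, H₂O₂ 0.70, H⁺ 3.24, OH⁻ 0.68 per 100 eV — a standard low-LET
1 µs set; 1 species/100 eV ↦ 0.10364 µM/Gy) plus the neutral-water
background, in a volume of 2·10⁻¹¹ L so that every reactive species
counts ≥10⁴ molecules (the smallest, H₂, ~5.6·10⁵). One hundred seeded
replicates are averaged and compared with the deterministic solution on
a common log-time grid up to steady state (1 ms), excluding points where
both solutions are under 10⁻¹² M. The measured maximum per-species ratio
deviation is ~0.2%, dominated by the Monte-Carlo noise of e⁻aq once it
has decayed to ~10⁻¹⁰ M; the volume was sized for exactly this — giving
the late-time minority species enough molecules for percent-level
replicate means — and the criterion is met with margin.

## Track generator

The physical and physico-chemical stages are replaced by a parametric
model of their net output. A primary crosses the box along +z (protons of
tens of MeV are effectively straight over µm chords; entry point uniform
on the face). Deposition clusters are placed with Poisson statistics so
the expected energy per unit length equals the unrestricted LET
(0.96 keV/µm for 70 MeV protons, interpolated log-log from a vendored
PSTAR-style stopping-power excerpt); cluster energies are exponential
(mean 40 eV) — the simplest straggling model with the correct mean.
Species are drawn multinomially from hand-off yields (defaults:
e⁻aq 4.6, •OH 5.1, H• 0.62, H₂ 0.15, H⁺ 4.6 per 100 eV — literature-
informed placeholders for the pre-recombination yields, with H⁺ tied to
e⁻aq for charge neutrality and pre-chemical OH⁻ not modelled) and
scattered around the axis with a Gaussian of σ = 4 nm. The booked energy
of a track is the sum of its cluster energies, making the
counts-per-energy G-value an unbiased round trip of the input yields.

`calibrate_handoff` closes the loop against target 1 µs escape yields: a
fixed-point iteration scales each hand-off yield by
(target/achieved)^0.7 under common random numbers, with H₂O₂ steering
its radical precursor •OH (square-root weight). Species that arrive at
only a few particles per forward run (H₂, H₂O₂ at desk scale) carry
Poisson noise of tens of percent; calibrations at that scale should fit
the abundant species and treat the minority residuals as indicative.

## Beam orchestration and thresholds

The orchestrator enforces Dp = D̊p·FWHM, D̊av = Dp·f, non-overlapping
pulses (f·FWHM < 1), and N = round(D·ρ·L³/(LET·L)) primaries per pulse
(ρ = 1000 kg/m³; thin-target constant LET). Arrival times are uniform in
the top-hat pulse window. After each pulse the particle stage runs to
FWHM + t_hom (default 10 µs — a conservative homogenisation horizon, the
hand-off point being a free choice of the method), then counts convert to
concentrations (C = n/(N_A·L³)), the rate equations run to the next pulse
start, and survivors re-particlise at uniform random positions —
justified because they are homogeneous by then. Sub-particle
concentration remainders and the immobile sink are carried in a molar
residual rather than lost to rounding, so the particle↔concentration
round trip is exact. Dose bookkeeping compares booked energy against the
N·LET·L expectation; the tolerance must accommodate the Poisson
straggling of cluster counts, a few percent at desk scale (hundreds of
clusters) and sub-percent at full scale.

Fast mode replaces each pulse by an instantaneous concentration
injection sized from the escape yields — valid when the intra-track
(sub-µs) chemistry is summarised by those yields — and is what the
threshold and dose-response scans use.

The build-up threshold is defined operationally: the smallest D̊av on an
ascending grid (8 points/decade over 0.01–10⁵ Gy/s) at which, just
before the final pulse, the most persistent radical (max over e⁻aq, •OH,
H•) retains more than 5% of its post-pulse peak. The 5% criterion is this
package's choice — the underlying transition is gradual and is always
reported as an order of magnitude (nearest power of ten). With the
default yields the thresholds land at 10 Gy/s for D̊p = 2·10⁵ Gy/s
(0.2 Gy pulses) and 100 Gy/s for 10⁶ Gy/s (1 Gy pulses); the scaling with
pulse dose rate follows from second-order radical kinetics (depletion
time ∝ 1/concentration ∝ 1/Dp, period ∝ Dp/D̊av).

H₂O₂ dose-response scans fit a straight line to the post-irradiation
concentration at 1, 5, 10, 15 and 20 Gy; the slope, converted with
0.10364 µM/Gy, is the reported yield. Because those dose points are
unevenly spaced, the concavity ("root-like") property is assessed with
divided differences (decreasing chord slopes), not raw second
differences.

## What the synthetic data do and do not show

The generator emulates the *net* hand-off of the early stages — energy
budget, yield proportions, radial spread — not their mechanism: no
cross-sections, no delta-ray transport, no dissociation branching, no
build-up/backscatter bookkeeping at the box faces. Escape-yield
injections likewise compress all intra-track chemistry into one vector.
Tests passing on these inputs validate the chemistry engines, the
periodic boundaries, the pulse bookkeeping and the build-up mechanism;
they do not validate absolute single-track G₀ kinetics against
experiment, which would require the real physico-chemical stage.
Desk-scale runs also use boxes down to 0.1 µm and thousands (not
billions) of particles; finite-size independence is itself verified, but
Monte-Carlo bands at those counts are percent-level at best.

## Numerical choices and limitations

* Tie-breaks in the reaction sweep are nearest-first with seeded random
  resolution of exact ties; runs are bit-reproducible under a fixed seed
  (per-engine: the compiled and reference sweeps consume randomness
  differently and match only statistically).
* The comparison metric floors concentrations at 10⁻¹² M to avoid 0/0
  ratios of empty species.
* Background H⁺/OH⁻ are not represented as particles (≪1 per box); they
  exist only in the concentration solvers.
* Oxygen and pH-dependent chemistry, temperature dependence, partially
  diffusion-controlled reactions, electric-field and spin effects, and
  the independent-reaction-time method are out of scope.
* The particle engine's effective rates are schedule-dependent (see
  above); conclusions drawn from it here are either schedule-matched
  comparisons or use diffusion-resolved radii.
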