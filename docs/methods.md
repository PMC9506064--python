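# Methods

This note documents the models, discretizations, parameter choices and
known limitations behind `localep`. All defaults live in
`localep.params`; configuration files can override any of them.

## Membrane electroporation model

Electroporation is represented by the asymptotic pore-density model:
each membrane element carries an areal density *N* (m⁻²) of
fixed-radius hydrophilic pores,

> dN/dt = α e^{u²} (1 − (N/N₀) e^{−q u²}),  u = U_cm / V_ep,

with creation prefactor α = 10⁹ m⁻²s⁻¹, resting density
N₀ = 1.5×10⁹ m⁻², characteristic voltage V_ep = 0.25 V and
q = 2.46. Pores have fixed radius r_p = 1 nm; pore expansion,
resealing after the pulse, temperature effects and molecular transport
through pores are outside scope. The conductance added by the pores is
that of N parallel cylinders with access resistance,
G_ep = N·2σ_p π r_p²/(π r_p + 2 d_m), with the in-pore conductivity
σ_p = (σ_e − σ_i)/ln(σ_e/σ_i) ≈ 0.910 S/m, the logarithmic mean of the
bath (1.5 S/m) and cytoplasm (0.5 S/m) conductivities. Membrane
passives: G_cm = 2 S/m², C_cm = 0.01 F/m², d_m = 5 nm.

**Time stepping.** With the transmembrane voltage frozen over a step,
the rate law is *linear* in N and solves exactly:
N(t+Δt) = N_eq + (N − N_eq)e^{−kΔt}, with
N_eq = N₀e^{q u²} and k = (α/N₀)e^{(1−q)u²}. The production stepper
uses this closed form — unconditionally stable, exact for any Δt —
instead of a generic stiff integrator. Numerical care: the creation
term is evaluated through the identity N_eq·k = α e^{u²} in log space,
because at large |U| (which occurs transiently inside nonlinear field
iterations) N_eq overflows while k underflows, and the naive
formulation silently loses the creation term. Exponents are clipped at
a numerical ceiling N ≤ 10²² m⁻², far above the self-limited densities
the coupled model reaches (≲10¹⁶ m⁻²). An adaptive BDF integrator
(`integrate_density`) is provided for continuously interpolated
voltage histories; a fixed-step RK4 reference at 1 ns cross-checks it
in the tests. Default coupling mode is frozen-per-field-step.

## Cell-scale unit cell

One adherent cell — a half oblate spheroid (height × largest semiaxis
15×40 µm by default; 7×20 µm as the small variant) with its flat face
100 nm above the substrate — sits on a square lattice of substrate
pores with pitch 1/√ρ, reproducing the manufacturer porosity exactly.
The unit-cell square has side 2a (cells tiling the substrate); lattice
pores outside the circular footprint short the two reservoirs directly
and only enter the current bookkeeping.

The discretization is a pseudo-3D nonlinear network chosen so each
controlling resistance is explicit:

* **Pore conduit** (per lattice site): cylindrical channel
  d/(σ_e π r²) plus bottom-side half-space access 1/(4σ_e r), plus an
  expansion term when the pore is narrower than the gap. The top-side
  access into the gap is *not* lumped here — it is resolved by the
  annular film below.
* **Gap film**: the 100 nm cell–substrate gap is a laterally
  conducting sheet (conductance σ_e·h per square). Around every pore
  mouth it is refined into log-spaced annular ring nodes from r_p out
  to the equal-area site radius (ratio ≤ 1.5 per ring, so the membrane
  above a mouth is resolved below r_p/2). Neighbouring sites couple
  through standard square-lattice sheet links; rim sites drain into
  the bath through the film plus a bulk access term.
* **Membrane elements**: one disc element above each pore mouth plus
  one element per annulus (substrate-facing class), and one
  slant-area-weighted dome element per site (dome class), each with
  its own N, conductance and capacitance (implicit-Euler companion
  model). Element areas are normalised so the classes sum exactly to
  the flat-face and dome areas.
* **Interior**: one node per site, laterally linked as a sheet whose
  thickness is the local dome height (σ_i = 0.5 S/m). This resolves
  interior lateral spreading and lets the dome porate gradually rather
  than all at once.

**Mouth sampling radius.** The membrane plane above a pore mouth does
not see the in-pore stagnation potential: the emerging current jet
expands across the gap before reaching the membrane. The mouth element
therefore samples the spreading film at an effective radius
r\* = 0.62 r_p + 0.24 h. The two coefficients were calibrated against
the independent fine-grid oracle (below), after which the
production/oracle mismatch in the pre-poration mouth transmembrane
voltage is ≤ 4% over pore diameters 0.1–1.0 µm and gaps 50–150 nm
(naive stagnation sampling errs by 11–27%). This is a calibration of
the lumped reduction against a resolved solve of the *same* model, not
against any external data.

**Drive.** The bottom reservoir is held at U_subs, the bath at 0; the
substrate dominates the series resistance so essentially the whole
assigned difference appears across substrate-plus-gap, matching the
convention in which U_subs denotes the assigned cross-substrate
voltage.

**Nonlinear time integration.** Steps follow a geometric time grid
(20 ns initial, ×1.3 growth, 0.25 ms cap — resolving the ~0.1 µs local
membrane charging and the ~30 µs global charging while covering 10 ms
in ~75 steps). Within each step the linear network (with membrane
companions) and the exact density update are iterated to a fixed point
damped in log N — the creation rate is doubly exponential in U, and
undamped iteration oscillates around the self-limited state. Damping
halves on error growth (floor 1/64); non-convergent steps bisect
recursively. Refining the grid tenfold changes end-of-pulse peak
densities by ≲10%, which does not move any onset grid point at the
default gap.

**Outputs.** `EpMap` holds per-element N at sampled times, areas,
classes and radial positions; `electroporated_area_fraction` uses the
detection threshold N > 10¹³ m⁻² (all membrane elements counted
identically, including those spanning pore mouths);
`onset_voltage_sweep` returns the first grid voltage with any element
above threshold. Everything is deterministic — the mesh derives from
geometry alone and there is no randomness in either solver.

## Verification oracles

`localep.oracle` provides a brute-force axisymmetric finite-volume
solver on nonuniform tensor grids (direct sparse factorization, films
as interface conductances, geometric stretching toward apertures to
resolve access constrictions). Three prepared geometries:

* **Single-pore patch**: one pore feeding the gap under a flat
  linearized membrane, rim and interior grounded. Verifies the site
  reduction on the quantity that controls onset — the pre-poration
  transmembrane voltage above the mouth (≤ 4–5% agreement, asserted in
  tests for 0.1–0.4 µm pores and 50–150 nm gaps; ~6–8% for 1.0–3.0 µm
  pores, where the closed-form conduit kernel itself carries a few
  percent of pore-crowding error).
* **Homogenized slab**: one pore between two reservoirs; its areal
  conductance matches the closed-form kernel within ~1% for 0.1–0.4 µm
  pores. The 1.0 µm substrate shows −4%: real proximity of pores at
  1.26% areal fraction, not discretization error.
* **Stacked-slab divider**: textbook series-resistor check.

The lattice level is checked separately against the analytic
uniform-leak fin solution (Bessel-I₀ profile of the gap potential
under the cell): centre buildup agrees to ~4%.

## Device-scale insert model

Axisymmetric finite-volume Laplace solve (default 0.1 mm cells) in two
liquid domains coupled column-by-column through the homogenized
substrate interface (normal current density G_subs,eff·U_subs; no
interface capacitance at steady state). Current is conserved to
machine precision; halving the mesh changes resistance by < 0.5%.

Geometry defaults (24-well hanging insert; exact radii are not printed
on datasheets, so they are configurable and recorded in every
manifest): substrate growth area 0.33 cm² (radius 3.24 mm), insert
nominal radius 4.1 mm, well radius 7.8 mm, substrate 0.8 mm above the
well bottom, 300 µL top liquid (5.7 mm column), top electrode standoff
2 mm, 0.5 mm Pt/Ir wire electrodes, σ = 1.5 S/m in both liquids. The
insert body tapers linearly from the substrate radius to the nominal
radius — a straight cylinder leaves an artificial annular shelf over
the insulating floor that corrupts the U_subs profile at the substrate
edge.

**Electrodes.** The spiral bottom electrode is modelled as a solid
plate (a spiral with enough turns is electrically equivalent); a ring
electrode is available for configuration studies and reproduces the
expected edge-concentrated, inhomogeneous U_subs. The L-shaped top
wire is axisymmetrized as an equipotential ring arc at the minimum
standoff whose circumference equals the immersed wire length
(≈ 7.8 mm → ring radius ≈ 1.24 mm); a plate top is also available.
The choice matters: a full plate top understates the solution-path
resistance by ~25 Ω (R ≈ 134/65 Ω and U_subs fractions ≈ 62%/28% for
the 0.4/1.0 µm substrates), while the wire-arc surrogate gives
R ≈ 156/90 Ω and fractions ≈ 53%/19%. Sensitivity to the surrogate
ring radius is ≈ ±15% in R over plausible radii (0.65–3 mm), which is
the dominant geometric uncertainty of the device model; electrode
electrochemistry (overpotentials, bubbles) is not modelled.

## Design calculators

Closed forms only: G_subs,eff and its reciprocal areal resistance;
pore areal fraction π r² ρ (proportional to diffusive solute flux);
translocation time t_trans = d²/(µ U_subs) with the in-pore field
approximated as U_subs/d (no access-resistance correction) and the
bulk unstained-DNA mobility 3.75×10⁻⁴ cm²/(V·s) as default. The
unfolded-translocation assumption is gated on the unstained radius of
gyration R_g = 0.110 µm (the stained value 0.131 µm is reported in the
warning text): a warning fires exactly when 2 R_g exceeds the pore
diameter — for 0.1 and 0.2 µm pores, not 0.4 µm.

## Synthetic pulse traces

`generate_trace` emulates oscilloscope recordings of capacitor-bank
pulses: per-pulse exponential droop (default τ = 50 ms, so a 10 ms
pulse droops mildly), Ohmic current, multiplicative gaussian noise,
fully determined by an integer seed. The resistance estimator defaults
to the least-squares V-against-I slope over the pulse window (unbiased
at zero noise for any droop; exact round-trip is asserted), with the
peak-ratio convention available. These traces are synthetic test
fixtures: they emulate generator droop and measurement noise only —
no electrode polarisation, cable artefacts or electroporation-induced
resistance changes — so passing round-trip tests demonstrates
estimator correctness, not instrument fidelity.

## Reference behaviour and known limitations

With the default parameter set the model reproduces the behaviour the
device is designed around: substrate conductances 365.5 and
1747.7 S/m² (0.4/1.0 µm); device resistances ≈ 156/90 Ω and substrate
voltage fractions ≈ 53%/19%; onset voltages on the {1, 2.5, 5, …} V
grid of 22.5/7.5/5/5 V for 0.1/0.2/0.3/0.4 µm pores at 2×10⁶ cm⁻²,
with both cell sizes agreeing for the 0.4 µm substrate; 1.0 µm onset
at 2.5 V with 43% of the membrane electroporated at 7.5 V, and the
3.0 µm substrate electroporating ≈ 59% at 7.5 V — the narrow-window
behaviour that disqualifies large pores for localized work.

Known limitations:

* **Gap knife-edge.** At the 0.4 µm substrate the 2.5 V pulse drives
  the peak density to 0.4–1.6×10¹³ m⁻² as the gap shrinks from 150 to
  50 nm, crossing the 10¹³ detection threshold near h ≈ 55 nm: the
  onset grid point flips from 5 V to 2.5 V at a 50 nm gap. The margin
  corresponds to ~3% in peak transmembrane voltage — inside the
  validated accuracy of the network reduction — so the model cannot
  resolve whether the onset is gap-robust at the 50 nm extreme; the
  corresponding invariant test is expected to fail and is left
  failing rather than widened.
* The total electropore count rises to ~60% of its end-of-pulse value
  within the first ~20 µs and then creeps (≥ 90% by 3 ms) as elements
  approach equilibrium at their clamped voltages; the early rise is
  fast but the plateau is not perfectly flat.
* The dome membrane porates per-site (one element per site), so
  dome-side spatial structure within a site is not resolved.
* The device model's absolute resistance inherits the top-electrode
  surrogate uncertainty (±15%); U_subs fractions are less sensitive.
* Post-pulse resealing, PI/DNA transport, Joule heating and
  electrode reactions are not modelled.
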