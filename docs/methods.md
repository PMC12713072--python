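# Methods

`lyosim` simulates a complete continuous-lyophilization cycle for a single
suspended glass vial: freezing with controlled or stochastic ice
nucleation, primary drying (sublimation), and secondary drying
(desorption).  In the suspended-vial configuration every vial travels the
same path through dedicated freezing and drying chambers, so one vial's
trajectory characterizes the whole process; there is no vial-to-vial
radiation network and no shelf contact — all heat transfer is convective
and radiative.

## Freezing

The product (solute + water, lumped at one temperature — the Biot number
for unit-dose vials is small) passes through five stages.

**Preconditioning.** Sensible cooling only:
`(m_s C_p,s + m_w C_p,w) dT/dt = Q_s1 + Q_s2 + Q_s3`, with Newton's-law
loads at the top (`h_s1`, driven by the upper chamber surface `T_u`) and
bottom (`h_s2`, driven by the gas `T_g`), and convection plus
fourth-power gray-body radiation (transfer factor `F_s3`, wall
temperature `T_c`) at the side.  The top and bottom coefficients fold in
linearized radiation; linearizing `T^4` exchange about the mean of the
two surfaces costs ~0.1% at a 20 K difference and ~2% at 100 K, which
the package exposes as `heat_transfer.linearization_error`.

**Vacuum-induced surface freezing (VISF).** The chamber is evacuated
(here as a 1-minute linear pressure ramp, matching how scheduled
set-point moves are modeled everywhere: steps become short ramps so the
stiff integrators see continuous right-hand sides).  Surface evaporation
`dm_w/dt = -h_m A_z (x_w,sat - x_w,c)` removes latent heat
`dH_vap(T) dm_w/dt` from the energy balance; the vapor-phase water mass
fractions follow from the partial pressures of water and inert gas.
When the saturation pressure exceeds the falling total pressure the
interfacial vapor is pure water and the driving fraction saturates at 1,
capping the flux at `h_m A_z`; this cap is what produces the
near-instantaneous temperature crash at deep VISF pressures while a
10 kPa hold takes on the order of ten minutes.  The liquid column height
(hence side area) is recomputed from the current mass by volume
additivity.

**Nucleation.** Deterministic mode fires when `T` reaches `T_n`.
Stochastic mode treats first nucleation as an inhomogeneous Poisson
process with intensity `lambda = k_n (T_f,l - T)^b_n V_l`; the survival
probability obeys `dP/dt = lambda (1 - P)` and is integrated alongside
the energy balance, with the event `P = u` for a single uniform draw per
run — exact inverse-CDF sampling of the first-event time.  No defaults
are shipped for `k_n`, `b_n` (they must be estimated per formulation);
ensembles in the test-suite use `k_n = 1e-7 m^-3 s^-1 K^-10`,
`b_n = 10`, order-of-magnitude representative of vial-scale water
nucleation kinetics.  The jump itself is instantaneous and adiabatic:
the energy balance `(T_f,l - T_n) C = m_i,n dH_fus` is solved
simultaneously with molal freezing-point depression
`T_f,w - T_f,l = K_f (m_s/M_s)/(m_w - m_i,n)` by bracketed root-finding
in `m_i,n` (the residual is monotone; the root is unique in
`[0, m_w)`).

**Solidification.** Ice grows from the bottom and side surfaces; the
shrinking liquid core is a cylinder geometrically similar to the initial
fill, the ice occupying a bottom slab plus the surrounding annulus
(volumes close exactly).  The ice acts as an extra series resistance:
the bottom load passes through the slab
(`U = 1/(1/h_s2 + l/k_i)`) and both the side convection and the
*linearized* side radiation pass through the cylindrical-shell
resistance `r_o ln(r_o/r)/k_i`.  The liquid temperature is slaved to the
depression curve `T = T_f,w - K_f (m_s/M_s)/m_w` with
`m_w = m_w(pre-jump) - m_i`, which reduces the stage to a single ODE:
`dm_i/dt = sum(Q) / (C_eff dT/dm_i - dH_fus)`.  Differentiating the
algebraic constraint avoids a DAE while keeping the printed equations
satisfied identically (the slaving residual is checked to < 1e-9 K in
the tests).  The stage ends at `m_i = f m_w(post-jump)` with `f = 0.95`
by default; moving `f` across 0.85–0.95 shifts the total freezing time
by only a few percent (regression-tested at < 10%).

**Final cooling.** Sensible cooling of the frozen product (heat capacity
including residual water and ice) at fixed geometry, to a configurable
handoff temperature (default 235 K).

## Primary drying

One-dimensional heat conduction in the frozen region `S(t) < z < H`
(`z = 0` at the cake top) with side-wall radiation as a local volumetric
source `4 sigma F_s3 (T_c^4 - T^4)/d` (side area over frozen volume is
`4/d` regardless of the frozen height, and using the local node
temperature keeps the source finite as the layer vanishes).  The front
recedes at `dS/dt = N_w/(rho_f - rho_e)` with sublimation flux
`N_w = (p_sat,ice(T_front) - p_w,c)/R_p(S)` against the empirical cake
resistance `R_p = R_p0 + R_p1 S/(R_p2 + S)`; the flux is floored at zero
(the chamber cannot push vapor back into the cake).  Boundary
conditions: Newton's law at the bottom (`h_b`, shelf `T_b`) and the
front energy balance
`N_w dH_sub = k_f dT/dz + sigma F_s1 (T_u^4 - T^4)` at `z = S`.

The moving domain is mapped to `xi = (z - S)/(H - S)` and discretized
with second-order central differences; both boundary conditions are
imposed by ghost-point elimination at `j = 1` (front) and `j = n_z`
(bottom).  The resulting stiff ODE system (default `n_z = 25`,
`rtol = 1e-6`) is integrated with BDF.  The transformation is singular
at `S = H`, so the front starts at a floor `S = 1e-6 H` and the terminal
event fires at `S = (1 - 1e-4) H`; the reported drying time
extrapolates the final front velocity to `S = H` (the correction is
< 0.1% of `t_d1`, and doubling `n_z` moves `t_d1` by < 1%).

The thermal-gradient demonstration (thick 20 mm sample, `h_b = 30
W m^-2 K^-1`) is built on the validated primary-drying parameter set
(shelf at 263 K, fitted cake resistance `R_p1 = 3.4e7`, `R_p2 = 1`):
with that set the early-time vertical temperature difference is ~6 K and
decays as the front recedes.  The gradient is reported once the front
motion is quasi-steady, taken as the time the front passes 5% of the
product height; it is sensitive to the cake-resistance constants (with
the generic default resistances the colder front steepens the early
gradient to ~9 K).

## Secondary drying

Heat conduction through the dried cake (effective properties `rho_e`,
`C_p,e`, `k_e`) with the same bottom film coefficient as primary drying,
a radiative top boundary, the same volumetric side source, and
linear-driving-force desorption `dc_w/dt = -f_a exp(-E_a/RT) c_w`
(equilibrium loading taken as zero; configurable) entering the energy
balance as a distributed sink `rho_d dH_des dc_w/dt`.  Vapor transport
through the cake is omitted — desorption is the rate-limiting step at
these conditions.  The run ends when the trapezoid-mean of `c_w` over
`z` (matching total-moisture measurements such as Karl Fischer) reaches
the residual target `c_w,inf` (default 0.01 kg/kg).  In the isothermal
limit the mean concentration is exactly exponential, which serves as the
module's closed-form oracle.

Two desorption parameter sets are shipped: the generic defaults
(`f_a = 1.5e-3 s^-1`, `E_a = 6500 J/mol`) and the data-fitted set
(`f_a = 0.42`, `E_a = 2.05e4`) used by the validation cases 3a/3b; no
reconciliation between them is attempted.

## Chamber / condenser balance

For condenser-failure studies the chamber water partial pressure becomes
a state: `dp_w,c/dt = (j_w - j_w,max) R T_bar/(V_c M_w)` with
`j_w = n_vial A_z N_w`, coupled two-way with the primary-drying solver.
Excess condenser capacity only works off accumulated vapor: the removal
is floored at the operating setpoint (initial `p_w,c`), so an oversized
condenser reproduces constant-pressure operation exactly and the
pressure can never go negative.  The chamber relaxation time
(`R_p V_c M_w / (n_vial A_z R T_bar)` ~ 0.2 s) is far shorter than the
thermal timescale, so the pressure rides a quasi-steady manifold
`p = p_sat,ice(T_front) - R_p N_w*` that climbs as the product warms and
peaks when the front temperature reaches its steady value — the
"plateau" is that broad maximum (~23 Pa here, reached in under an
hour), after which cake-resistance growth lets the pressure relax
slowly.  The plateau level shifts by >3 Pa per 1.5 K of steady front
temperature, i.e., it inherits the full sensitivity of the ice
saturation curve.

## Cycle orchestration and reproducibility

`run_full_cycle` stitches the stages: primary drying starts uniformly at
the freezing end temperature; secondary drying inherits the primary end
profile (the frozen remnant is a thin, near-isothermal layer at the
bottom; its profile is interpolated onto the cake grid) and the
configured uniform initial moisture.  Handoff continuity is asserted,
and stage times add exactly to the cycle time.  All randomness flows
from one root seed: ensembles draw per-run uniforms from
`numpy.random.default_rng(seed)`, so run *i* of an ensemble equals a
single seeded run, and identical seeds give bit-identical trajectories.
A default full cycle (freeze ~1.2 h, primary ~5.7 h, secondary ~6 h of
process time) simulates in a few hundred milliseconds.

## What the bundled scenarios do and do not represent

Scenario fixtures (`lyosim.cases`) encode the documented parameter sets:
the default full cycle, single-stage validation cases (1, 2a/2b, 3a/3b),
the VISF pressure study, the condenser-failure analysis, and the
gradient demonstration.  The measured gas-temperature trace for the
freezing validation is not bundled; case "1" substitutes a synthetic
constant cold-gas hold, so that case exercises the machinery but not the
experimental comparison.  Constant thermophysical properties, a flat
sublimation front, a single lumped freezing temperature and the absence
of vial-to-vial coupling are modeling choices appropriate for unit-dose
suspended vials; passing tests demonstrate internal consistency and
agreement with the printed reference quantities, not validity outside
that regime (large vessels, batch shelf contact, multi-row radiation).

## Numerical choices

LSODA integrates the small freezing ODE systems, BDF the method-of-lines
drying systems; all stage transitions are located by terminal events
(temperature crossing, probability crossing, ice-fraction criterion,
front arrival, moisture target).  Tolerances default to `rtol = 1e-6`
with state-appropriate absolute tolerances (1e-8 K, 1e-15 kg, 1e-12 m).
Degenerate inputs fail loudly: zero emissivity, inverted shell geometry,
nucleation above the equilibrium freezing point, stochastic mode without
kinetics, and an already-dry initial cake (which terminates
immediately).
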