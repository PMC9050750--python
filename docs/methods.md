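# Methods

## The pump model

`pump_model` treats the epithelium as a serial chain of compartments:
apical bath → cell → lateral intercellular cleft → basal bath. Each
water pathway is a Kedem–Katchalsky element, J = L_p[ΔP − σRT Δc], with
hydraulic conductivities L_a (apical membrane), L_b (basolateral
membrane) and K_s (the cleft exit to the basal bath, purely hydraulic:
no membrane, so no osmotic term). The solute is a single ideal,
charge-neutral species. It crosses the membranes passively
(permeabilities g_a, g_b), drains diffusively out of the cleft
(coefficient k_d) and is carried advectively out of the cleft by the
volume flow (term J·c_s). On top of the passive paths the cell pumps the
solute trans-cellularly: an active influx across the apical membrane and
an equal active efflux across the basolateral membrane, at rate A
(mol m⁻² s⁻¹). This through-pumping enriches the cleft, the standing
osmotic gradient draws water across the epithelium, and an opposing
hydrostatic gradient ΔP = P_basal − P_apical reduces the flux until it
stalls.

Steady state imposes five balances (three equal water fluxes, two solute
balances). Because the solute balances are linear once J is fixed, and
summing the three water equations returns J from the cleft osmolarity,

    J (1/L_a + 1/L_b + 1/K_s) = (P_a − P_b) + RTσ (c_s − c_a),

the whole system reduces to one scalar equation in J. The solver
brackets this monotone scalar equation and applies Brent's method
(xtol 1e-22, rtol ~9e-16), then back-substitutes the compartment
pressures and concentrations and verifies a normalised residual below
1e-10. It is deterministic and needs no initial guess or damping. An
independent damped fixed-point iteration of the same balances lives in
the test suite as a cross-check.

Setting J = 0 in the balances gives the closed-form stall for a constant
active flux and isotonic baths,

    ΔP* = ± RTσ A / (k_d + G),   G = g_a g_b / (g_a + g_b),

(positive for absorptive, negative for secretory orientation). The
numerical root-finder reproduces this to better than 1e-6 relative error
across randomised parameter sweeps. For general baths the same algebra
gives ΔP* = RTσ[k_d(c_b − c_a) + A]/(G + k_d): osmotic dilution of the
upstream bath leaks into the stall only through the (small) diffusive
cleft drainage k_d.

Two details depart from the most literal transcription of the balances:

* **Active-flux placement.** The active term acts at *both* membranes
  (influx apically, efflux basolaterally). A one-sided placement is
  configurable through `apical_fraction` / `basal_fraction`, but the
  symmetric through-pump is the default: it is the configuration whose
  stall obeys the closed form above, and the one consistent with an ion
  pump moving solute all the way across the cell.
* **Upwinded cleft advection.** The advective export term is J·c_s for
  forward flow but J·c_b when the flow reverses — inflowing basal fluid
  carries the basal concentration. Without upwinding the balance becomes
  unphysical (and singular) under strong reverse flow, e.g. while
  sweeping a PPC far past stall.

### Active-flux variants

* `constant`: A = A₀.
* `osmotic_linear`: A = A₀[1 + α·RTσ(c_a − c_b)/Π_ref], the active rate
  responding linearly to the trans-epithelial osmotic pressure
  difference. With α = −1 and Π_ref equal to the baseline osmotic
  pressure (RTσ·300 ≈ 7.73×10⁵ Pa), a 20 % apical dilution raises A by
  20 %. Because A sets the stall directly, this variant produces a PPC
  family whose stall *shifts* with osmolarity.
* `apical_pressure`: A = A₀·max(0, 1 − P_a/P_sat), extinguishing as the
  apical hydraulic pressure approaches P_sat. The active rate does not
  read osmolarity at all, so with small k_d the stall is *insensitive*
  to dilution while J₀ still shifts through the passive osmotic driving
  force — the converging PPC family. P_a is the apical bath pressure
  (which varies along S2 sweeps and is constant along S1 sweeps).

All variants clip at zero. The dichotomy between the last two variants
is the model's account of why some epithelia shift their stall under
hypo-osmotic challenge while others converge to a fixed stall.

### Reference parameter sets (calibration choices)

Two parameter sets ship as package data. They are calibration choices of
this package, made once to land the descriptors in the experimentally
reported ranges, not measured constants:

| parameter | mdck_normal | adpkd_cystic | units |
|---|---|---|---|
| L_a = L_b = K_s | 1.5e-9 | 1.5e-9 | m Pa⁻¹ s⁻¹ |
| g_a = g_b | 2.6e-4 | 2.6e-4 | m s⁻¹ |
| k_d | 2.0e-9 | 2.0e-9 | m s⁻¹ |
| A₀ (constant variant) | 1.009e-5 | 1.5134e-5 | mol m⁻² s⁻¹ |
| orientation | absorptive | secretory | — |

With RTσ = 2577 J mol⁻¹ (310 K, σ = 1) these give an isotonic stall of
+200 Pa (normal) and −300 Pa (cystic), and a device-level zero-pressure
flux of ≈ +1.09 / −1.63 µL h⁻¹ over the 12 mm² window. k_d is chosen
small relative to G (ratio ~8×10⁻⁶) so the cleft drains almost entirely
advectively; this is what keeps the apical-pressure variant's stall
within a few per cent across 10–50 % dilutions while the osmotic-linear
variant shifts by tens of per cent. The per-cell force at stall uses a
400 µm² footprint (80 nN for the normal set).

Limitations of the model: no ionic species or membrane potentials, no
cell–cell coupling, no regulatory feedback on the pump other than the
explicit variants, and a lumped (not spatially resolved) cleft. Mirror
symmetry between orientations is exact at stall but only approximate
(to ~J/(G+k_d), relative) for flowing states, because the cleft sits on
the basal side in both orientations.

## Device hydraulics

Pressure from column height is ρgh − offset, with ρ = 1020 kg m⁻³ for
culture medium, g = 9.81 m s⁻², and a constant per-device capillary-
action offset taken from blank calibration (a required config input; no
time dependence is modelled). Flux is the rolling least-squares slope of
height vs time multiplied by the capillary cross-section
(0.31 mm² → 0.31 µL per mm graduation; one graduation of medium is
10 Pa). Windowed regression is used instead of finite differences
because readings are quantised to the ruler graduation.

`ppc_from_trace` pairs each window-centre head (signed per setup: S1
reads the basal column so ΔP = +head; S2 reads the apical column so
ΔP = −head and the filling rate is negated to keep J positive
apical→basal) with the window's flux. Quantised heights produce tied ΔP
values; ties are averaged so the curve keeps strictly increasing ΔP.

The default slope window is 11 samples, suited to smooth or lightly
quantised traces. For hour-scale stall runs read at 60 s frames and
quantised at 1 mm, the expected height change inside a window must
exceed the graduation for the slope to be informative; the demo pipeline
and the end-to-end checks therefore use a 101-sample (~1.7 h) window,
which recovers the generating stall within 5 % and J₀ within 10 % at
0.2 mm reading noise.

Shear ↔ flow conversions use the wide-slot (parallel-plate)
approximation Q = τwh²/(6µ); at the channel's 8:1 aspect ratio the error
against the full rectangular-duct series is below 10 %, acceptable for
setting shear-stress levels.

## Estimation

The default PPC fit is an ordinary least-squares line (printed PPCs are
near-linear): J₀ is the intercept, ΔP* = −J₀/slope. An
isotonic-decreasing fit with interpolated zero crossing is available
when curvature matters. Stalls estimated without an observed sign change
in J are *flagged* as extrapolated rather than refused, because a device
may stall before its column crosses ΔP*. Positive fitted slopes warn
(non-pump-like). Per-curve uncertainty is a case-resampling percentile
bootstrap (2.5/97.5), deterministic given the seed; degenerate resamples
(all ΔP equal) are skipped and counted. Measured coverage for the stall
CI at the study noise level is ~92 % nominal 95 %. Group comparisons use
the two-sided Mann–Whitney test, exact for both groups ≤ 10 without
ties, otherwise the normal approximation with mid-rank tie correction
(flagged). No multiple-testing correction is applied; comparisons are
reported per contrast.

## Synthetic data

`simulate_capillary_trace` integrates the column ODE
dh/dt = s·J(ΔP(h))·A_epi/A_mc (s = ±1 per setup) with an adaptive RK45
scheme (rtol 1e-8) — the system is stiff-free at these scales — then
samples at the frame interval, adds Gaussian reading noise (default
0.2 mm, a plausible videography readout error) and rounds to the 1 mm
graduation. The pre-noise solution is monotone. The generator captures
the saturating rise-to-stall shape, readout noise and quantisation of
real traces, but not evaporation, CO₂ buffering, temperature drift, or
biological drift in the pump itself; recovery results on synthetic
traces therefore bound the estimator's statistical error, not these
systematic effects. PPC point sets are sampled from the exact pump line
with Gaussian flux noise, and qPCR tables encode programmed fold changes
as CT shifts of −log₂(fold) against a constant housekeeping baseline.
All generators take explicit integer seeds and are bitwise reproducible.

## qPCR statistics

Relative amounts use the ΔCT method, RQ = 2^−(CT_gene − CT_hk), with
18S rRNA as the default housekeeping gene; samples whose housekeeping
reaction is missing (or at/above an optional background threshold) are
dropped with a warning. The threshold default is "missing only", since
no universal numeric cutoff exists. Heatmap rows are standardised with
the population (divisor n) standard deviation, matching the Z-score
definition Z = (χ − µ)/σ with population moments; constant rows raise an
error naming the gene. A ΔΔCT convenience wrapper contrasts group means.
Primer-efficiency correction and clustering are out of scope.

## Dome pressure

Young–Laplace with a spherical-cap meniscus, P = 2γ/R + P_ref, is the
default; a cylindrical option (γ/R) is behind a flag since the meniscus
geometry is not always known. The oil–media interfacial tension γ is a
required user input. Dome wall tension uses the thin-shell law PR/2.
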