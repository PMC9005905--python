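# Methods

## Scope

`pulsetree` simulates pulse-wave propagation in a reduced systemic
arterial tree under staged removal of the renal circulation and
measures regional pulse wave velocity (PWV) from the simulated pressure
waveforms with the clinical foot-to-foot method. This note records the
governing equations, the constitutive and boundary models, the
calibration of open parameters, the numerical choices, and what the
packaged synthetic fixtures do and do not represent.

## Governing equations

Each vessel segment is a tapered 1-D tube. Averaging the
incompressible Navier–Stokes equations over the cross-section gives

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A)/∂x + (A/ρ) ∂P/∂x = − k_f (μ/ρ) (Q/A)

with area `A`, flow `Q`, pressure `P`, blood density `ρ = 1050 kg/m³`
and viscosity `μ = 4 mPa·s`. The friction constant `k_f = 2π(ζ+2)` with
`ζ = 9` corresponds to a near-plug axial velocity profile; Womersley
(frequency-dependent) friction is not modelled. The momentum correction
factor of the convective term is taken as 1.

ρ = 1050 kg/m³ is also the unique density (to ~±5 kg/m³) for which the
package's published distensibility → PWV reference table is internally
consistent under Bramwell–Hill; a brute-force scan has its optimum near
1055 kg/m³, and at 1050 a single table cell (dorsal, in-vivo column)
disagrees by 0.002 m/s beyond the printed precision — a rounding
artefact of the source table, not of the implementation.

## Tube laws

Distensibility is declared per segment at the reference pressure
`P_ref = 100 mmHg`; a tube law extends it to a full `P(A)` relation.
Four are implemented (`WallModelParams.tube_law_kind`):

* `linear` — `P = P_ref + (A − A0)/(D_ref A0)`. Used by the
  solver-validation fixtures because its wave speed at the reference
  point is exactly the Bramwell–Hill speed of the declared
  distensibility.
* `power` — `P = P_ref + ((A/A0)^m − 1)/(D_ref m)`; `m` may be set per
  node as `2σ/D_ref` to prescribe a uniform relative wave-speed
  pressure-sensitivity σ.
* `exponential` — wave speed prescribed directly,
  `c² = exp(2σ(P−P_ref))/(ρ D_ref)` below the reference and
  `c² = (1 + 2σ(P−P_ref))/(ρ D_ref)` above it (C¹-matched), with σ
  growing for smaller lumen diameters.
* `arctan` (default) —
  `A(P) = A_m (1/2 + arctan((P−P0)/P1)/π)`, the classic sigmoidal
  pressure–area curve of arteries. Per node, `(A_m, P1)` are solved so
  that area and distensibility at `P_ref` match their declared values.
  The inflection `P0` is 45 mmHg for vessels ≥ 8 mm, rising linearly to
  55 mmHg below 3 mm: muscular arteries keep their compliance peak
  closer to working pressures, so their wave speed reacts more strongly
  to a pressure change. Of the two admissible `P1` roots the narrower
  ("stiff") branch is used; the wider ("gentle") branch is available.

The arctan/stiff default is what gives the package its physiological
PWV behaviour: wave speeds at diastolic pressures are well below the
reference Bramwell–Hill values (the wave foot travels on the lower,
more compliant part of the curve), they rise steeply with blood
pressure, and — because a distensibility reduction re-anchors the curve
at `P_ref` — stiffening a large compliant vessel changes its diastolic
wave speed much less than its reference speed. All three properties are
needed to reproduce the observed behaviour of foot-to-foot PWV under
kidney removal and under imposed wall stiffening.

## Boundary conditions

**Root.** A time-varying elastance ventricle,
`P_lv = E(t)(V − V0)`, with `E(t)` a double-Hill activation normalised
to peak 1 at `t_peak_frac·T`. An ideal valve with series resistance
couples the chamber to the root: it opens when `P_lv` exceeds root
pressure and closes on flow reversal; no regurgitation, atrium or
inertance is modelled. Filling is drawn from a constant preload
pressure through a filling resistance. A prescribed periodic inflow
waveform can replace the ventricle for controlled experiments.

Defaults (`E_max 1.2`, `E_min 0.08 mmHg/mL`, `V0 15 mL`, `T 0.8 s`,
`t_peak_frac 0.38`, preload `14.5 mmHg`, valve `0.05 mmHg·s/mL`) are a
calibration, not a transcription: they target heart rate 75 bpm,
cardiac output ≈ 5 L/min, aortic pressure ≈ 118/73 mmHg on the
reference tree, and an afterload sensitivity such that removing both
renal beds raises aortic systolic pressure by roughly 9 mmHg rather
than the ~20 mmHg a flow-source heart would produce.

**Terminals.** Three-element Windkessels. Total peripheral resistance
distributes the target cardiac output over the beds according to fixed
resting flow fractions (renal 9% each, splanchnic 28.5%, head 16%,
limbs and coronary the rest). `R1` is the characteristic impedance of
the feeding segment (capped at 0.8 of the bed total), which minimises
non-physiological terminal reflections. A lumped compliance of
1.3 mL/mmHg is shared across beds in proportion to flow, with the renal
beds at half weight (muscular, low-compliance organs). Venous outflow
pressure is 5 mmHg.

**Junctions.** Mass conservation and continuity of total pressure
`P + ρu²/2`, solved per time step together with the outgoing
characteristic compatibility relation of each adjoining vessel end
(Newton iteration on the common total pressure, converged to a flow
residual below 10⁻¹³ m³/s).

## Numerics

Richtmyer two-step Lax–Wendroff in finite-volume form: cell-centred
states, half-step face fluxes, boundary fluxes from the characteristic
solves. Because every face flux is single-valued and junction solves
balance flow exactly, the scheme conserves volume to round-off — the
inflow and summed terminal outflow volumes of a converged cycle agree
to much better than the 1% acceptance bound. A Rusanov-type face
dissipation (coefficient 0.6, acting on the deviation of area from the
reference taper so that a tapered rest state is an exact equilibrium)
keeps the steep nonlinear fronts monotone; it plays the role of the
wall viscoelasticity that the model omits. Defaults: cell size 1 cm,
time step 10⁻⁴ s (CFL-checked against the fastest characteristic),
initial state 90 mmHg everywhere at zero flow, up to 12–14 cycles with
convergence declared when no site pressure changes by more than
0.3–0.5 mmHg between cycles. Non-convergence warns and is flagged in
the result, never silently accepted. Waveforms are analysed on the
final cycle, Fourier-resampled to 900 Hz.

## PWV measurement

The foot of each 900 Hz pressure waveform is located on a smoothed copy
(zero-phase 4th-order Butterworth low-pass, 25 Hz) as a maximum of the
second derivative on the systolic upstroke. Two robustness rules refine
the textbook "global maximum of d²P/dt²":

* the search window is anchored at the steepest point of the upstroke
  and extends backwards only to where the slope falls below 15% of its
  peak — searching the whole diastolic tail would let noise-induced
  curvature peaks on the flat baseline masquerade as the foot;
* within the window the *earliest* local maximum exceeding 50% of the
  window maximum is taken (with positive local slope). On waveforms
  with two-stage upstrokes — a moderate takeoff followed by a steeper,
  reflection-augmented rise, typical of stiffened configurations — the
  global maximum slides 30–50 ms up the wave and corrupts the transit
  time; the prominence rule keeps the foot at the takeoff.

Sub-sample refinement is by parabolic interpolation of the
second-derivative peak. Transit time is the foot-time difference
wrapped into one period; PWV is path distance over transit time, the
distance being the sum of segment lengths along the tree path through
the nearest common ancestor. Pressure metrics per cycle: SBP (global
maximum), end-DBP (end-diastolic minimum), early-DBP (first
post-systolic local minimum, reported as missing when no incisura
minimum exists), PP = SBP − end-DBP.

## Reference tree and calibration

The packaged two-kidney tree has 28 tapered segments: aorta with
coronary, brachiocephalic, carotid, subclavian→brachial→radial→palmar→
digital arm chain, lumped left-head/left-arm/splanchnic branches, both
renal arteries (ids 36 and 38, as in the study design), and two iliac
limbs — the right one continuing through the external iliac and femoral
artery to a lumped lower leg, the left one ending at the terminal
external iliac artery (id 44), the transplant target. Segment
dimensions follow the classic published systemic-tree tables;
per-territory distensibility uses the package's default table (aorta
27, carotid 23, femoral 10.6, brachial 7.3, radial 6.4 … kPa⁻¹·10⁻³),
with territories absent from the table (renal, mesenteric) filled from
the inverse-power diameter law `c = a·d^(−b)` calibrated through the
aortic and radial anchors.

Measurement sites are placed so the three path lengths are exactly
66 cm (carotid-femoral), 70 cm (carotid-radial) and 19 cm
(radial-digital); the carotid site sits low on the common carotid, so
the measured paths are dominated by the aortic and arm trunks. This is
a calibrated reduction of a much larger (143-segment) topology, not a
reproduction of it.

The transplant operation follows the study recipe: the target's
Windkessel is removed and the target becomes a junction feeding (a) a
new branch bearing the donor renal segment's geometry, wall and
Windkessel properties and (b) a short distal continuation inheriting
the original outflow, so downstream perfusion is preserved. (The source
description places the graft on segment 44 without giving a side in its
methods while its results text says "left external iliac"; the fixture
grafts onto the left external iliac, id 44.)

## Synthetic generators

* `make_single_tube_fixture` — one uniform segment with a
  characteristic-impedance-matched Windkessel and two sites 0.4 m
  apart; the analytic Bramwell–Hill speed rides along as ground truth.
  Used to verify that the solver's foot-to-foot speed matches the tube
  law within 5%.
* `make_delayed_pair` — a proximal/distal waveform pair where the
  distal is an exact analytic time shift of the proximal (non-integer
  sample delays represented exactly), with optional independent
  Gaussian noise under an explicit seed. The physiologic template is a
  double-exponential pulse with a sharp foot and a systolic rise of
  ~0.1 s; its foot, like that of real recordings, is a genuine kink —
  a smooth Gaussian bump template is also provided, and is deliberately
  harder for the estimator under noise.

These fixtures validate estimator and solver behaviour, not biological
variability: they contain no beat-to-beat variation, no baseline
wander, no sensor dynamics. Passing tests demonstrate numerical
correctness of the pipeline, not field performance on clinical signals.

## What the studies show, and known limitations

With all heart, wall and Windkessel parameters held fixed, removing
renal beds raises systolic pressure and pulse pressure at every site
and speeds up all three regional PWVs, medium-artery (carotid-radial)
PWV more than aortic (carotid-femoral) PWV; re-attaching one renal bed
on the iliac restores both pressures and PWVs to near the single-kidney
state. The diameter-stratified stiffening study (distensibility cut 40%
above 14 mm, 25% for 11–14 mm, 15% for 8–11 mm, 10% for 3–8 mm, 5% at
or below 3 mm, applied to the no-kidney tree) raises aortic systolic
pressure, lowers peak aortic flow and raises carotid-femoral PWV by
about a fifth.

Limitations worth keeping in mind:

* The wall is purely elastic; viscoelastic damping is mimicked only by
  the numerical face dissipation. Simulated upstrokes are therefore
  sharper than in the source model, which changes how far up the wave
  the detected foot sits. In particular, the carotid-radial PWV
  response to the diameter-stratified stiffening is much smaller here
  (≈ +9%) than the figure the original study reports (+40%); an
  analysis of the transit-time decomposition suggests the larger
  published figure depends on the global-maximum foot convention
  interacting with two-stage carotid upstrokes, which the robust foot
  rule used here deliberately avoids.
* Absolute peripheral PWVs depend strongly on the (unpublished)
  constitutive constants of the source model; the reduced tree
  reproduces relative changes and orderings more faithfully than
  absolute magnitudes.
* Coronary and cerebral networks are single lumped branches; no
  autoregulation, baroreflex, or venous circulation.
* The elastance heart has no atrium and a constant-pressure preload,
  so cardiac output responds to afterload only through the
  ventricular pressure-volume mechanics.
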