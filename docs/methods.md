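# Methods

`atriasim` is a desk-scale model chain for asking how fibrosis-associated
electromechanical remodeling degrades left-atrial (LA) pump function.  Nine
parameters altered in fibrotic myocardium — longitudinal and transverse
conduction velocity (CV_L, CV_T), three ionic conductances (I_K1, I_CaL,
I_Na), the myofilament binding rate (mu) and maximum active tension (T_a)
of the contraction model, and longitudinal/transverse passive stiffness
(ST_L, ST_T) — are switched between a baseline (B) and a fibrotic (F) level
inside the fibrotic region only, and the consequences are read off
pressure–volume (PV) loops.  This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## Synthetic cohort

Clinical inputs are summarized in three patient descriptors (end-diastolic
volume 110.0/112.5/60.0 mL; fibrosis burden 15.6/23.9/17.9 %; total LA
activation time 82.0/56.0/116.8 ms; CV_L 1.1500/1.5730/0.835 m/s; 1 Hz
pacing; 2 mm wall).  A `random` preset samples uniformly within the span of
these columns for larger test cohorts.

Geometry is an ellipsoid (semi-axis ratios 1 : 0.85 : 0.70) triangulated
from a subdivided icosahedron, radially perturbed by band-limited real
spherical harmonics (degrees 2–4, 5 % amplitude) and rescaled so the
enclosed cavity volume equals the descriptor's EDV exactly.  Angular caps
mark four pulmonary-vein ostia, a mitral cap, and an appendage patch; the
rest is body.  Labels are painted on the closed surface (no holes are cut),
so the mesh stays watertight.  The fiber field is the circumferential swirl
about the mitral axis projected into each triangle's plane — a stand-in for
rule-based atrial fiber maps, not a reproduction of one.  The LGE-like
intensity is iterated-neighbor-smoothed vertex noise rescaled to [0, 1],
which produces contiguous high-intensity patches.  What this emulates is
the *statistics* of a clinical input (a closed LA-like surface with smooth
patchy intensity); it does not emulate real LA anatomy, vein geometry,
regional wall thickness, or true LGE texture, so quantitative agreement
with the patient-specific 3D study is not expected and not claimed —
directional and protocol-level agreement is.

## Fibrosis mapping

Elements are ranked by descending intensity and marked fibrotic one by one
until the element-count fraction over body+appendage (veins and mitral cap
excluded, never fibrotic) first reaches the clinical burden; ties break by
element index.  Burden is a plain element-count fraction, not
area-weighted, matching the definition "percentage of mesh elements".  The
x1.5 "synthetically elevated" burden re-runs the same assignment at 1.5
times the achieved burden, which is exactly a lower intensity cutoff, so
elevated sets nest around the originals.

## Cell electrophysiology

The Courtemanche–Ramirez–Nattel (CRN) human atrial model is implemented in
full (21 states) with published constants and resting initial conditions.
Fibrotic remodeling scales the I_K1, I_CaL and I_Na maximal conductances by
0.5, 0.5 and 0.6.  The protocol is 50 beats at 1 Hz, dt = 0.025 ms,
stimulus −20 pA/pF for 2 ms; the final beat's membrane potential and
calcium transient are kept.

Numerics: Hodgkin–Huxley gates advance by Rush–Larsen; the membrane
potential and the five concentrations advance by a Heun
predictor–corrector.  Plain forward Euler for the non-gate variables was
tried first and left a 1.0 ms APD90 shift per dt-halving at dt = 0.025 ms;
the second-order update reduces that to 0.26 ms, which is what the
convergence test enforces.  An independently coded plain forward-Euler
integrator (run at dt/2) serves as the cross-check oracle and agrees with
the primary path to < 1 mV in resting potential and < 3 ms in APD90.

Halving I_K1 in the isolated cell elevates the pre-stimulus diastolic
potential by 7.4 mV and prolongs APD90 by 104 ms, and raises the calcium
transient amplitude; halving I_CaL roughly halves the calcium transient.
The source study reports ≈5 mV and ≈75 ms for the same perturbation, but
measured at points inside a 3D tissue simulation where electrotonic
coupling to non-fibrotic neighbours pulls the membrane toward baseline, and
with additional (unpublished here) modifications to the ionic model.  The
isolated-cell numbers are therefore expected to overshoot; the package
reports the honest isolated-cell values rather than tuning toward the
tissue figures.

## Contraction

A Land-type crossbridge/troponin model (states: troponin-C saturation,
blocked tropomyosin, weak and strong crossbridge fractions) runs at fixed
stretch on the CRN calcium transient.  Distortion states vanish identically
at constant stretch and are omitted.  Saturated tension is `t_a_ref`
(50 kPa baseline, so T_a is exactly linear in it); the myofilament binding
rate mu is expressed on the scale where the published unattached→weak
binding rate constant corresponds to mu = 9, i.e. the effective rate is
`k_uw * mu/9`.  This is an interpretation — the study names mu "myofilament
binding rate" with baseline 9 but does not print its identity — chosen so
that halving mu halves crossbridge recruitment and slows the twitch, the
stated functional consequence.  With baseline CRN calcium the twitch peaks
at 27 kPa at 108 ms, relaxing 90 % by ~220 ms after the peak.

## Passive material

Reduced Holzapfel–Ogden energy with a dispersed, tension-only fiber term:

    Psi = a/(2b) [exp(b(I1−3)) − 1]
        + a_f/(2 b_f) [exp(b_f (I4*−1)^2) − 1] · H(I4*−1),
    I4* = delta_f I1 + (1 − 3 delta_f) I4

with a = 2.92 kPa, b = 5.6, a_f = 11.84 kPa, b_f = 17.95, delta_f = 0.09
(kappa = 650 kPa for the penalty variant).  Virtual experiments stretch a
unit cube by 5 % along or across the fiber with traction-free lateral
faces; the reported load is the nominal normal traction on the stretched
face.  Incompressibility is exact by default (lateral stretches solved for
zero lateral Cauchy stress at det F = 1); a kappa-penalty variant
cross-checks it to within a few percent.  Stiffness calibration finds
multipliers (s_a, s_af) meeting target load factors in both directions to
< 1 %.

Which formulation the source study used is only determined up to its cited
references, so the printed calibrated pairs adjudicate: this formulation
reproduces the combined doubling as (2.000, 2.000) vs the printed
(2.009, 2.000) — within half a percent, the deviation of the printed pair
from exact homogeneity being a signature of their penalty-compressible FEM
— and the single-direction pairs as (1.000, 2.282) vs (0.963, 2.293) and
(2.000, 0.718) vs (2.157, 0.675).  The residual 4–8 % differences on the
single-direction pairs trace to the transverse experiment: under exact
incompressibility with free lateral faces the dispersed fiber invariant
stays below 1 during transverse stretch, so the transverse load carries no
a_f dependence at all, whereas the printed 0.963 implies a weak one.  The
formulation is isolated behind one function so alternative readings can be
swapped in.

For chamber coupling the wall stress uses the same law under equibiaxial
in-plane stretch (thickness 1/lambda² by incompressibility, zero transmural
stress); for lambda < 1 the fiber term switches off and the isotropic term
provides physiological compressive stress.

## Conduction

The stated anisotropy ratios (1:1/5 baseline, 1:1/8 fibrotic) are read as
*conductivity* ratios with CV ∝ sqrt(conductivity).  This inference is
adjudicated by the data: all three printed CV_T values equal CV_L/sqrt(5)
to print precision, and the printed fibrotic CV_T factor satisfies
0.657·sqrt((1/8)/(1/5)) = 0.5194 ≈ 0.520.

Activation maps come from a multi-ring (4-ring) Dijkstra solver on the
surface vertices in the Riemannian metric
`t(d) = |d| sqrt(cos²θ/CV_L² + sin²θ/CV_T²)`; vein and mitral caps are
non-conductive and unreachable-through.  On flat strips the solver is
within ~1.3 % of the closed-form arrival, the residual being graph
metrication error.  CV calibration inverts the patient's total activation
time for CV_L (CV_T slaved at 1:1/5): arrival times scale exactly as
1/CV_L, so the multiplicative update lands inside the 1 ms tolerance in
one or two iterations.

A 1D monodomain cable (CRN membrane, 20 mm, 0.1 mm spacing, operator-split
explicit diffusion with the step bounded for stability) tunes the
diffusivity to a target CV via the CV ∝ sqrt(D) law and, at fixed tuned
diffusivity, measures the emergent CV change under each ionic scaling
combination: I_Na×0.6 slows conduction ~20 %, I_CaL×0.5 is neutral, and
I_K1×0.5 speeds it marginally.  These ratios multiply the fibrotic-region
CV used by the eikonal solver, mirroring the tuneCV-style correction the
study applied to its prescribed velocities.

## Lumped hemodynamics

The deliberate headline simplification: the 3D electromechanics plus
closed-loop circulation is collapsed to a two-compartment 0D chamber in a
minimal CircAdapt-like loop.  The wall is split by element count into a
fibrotic fraction f and remainder 1−f; each compartment carries its own
active-tension transient (the fibrotic one delayed by the mean eikonal
arrival difference between fibrotic and non-fibrotic elements — spatial
dispersion collapsed to a delay) and its own passive material.  Cavity
pressure follows the one-fiber relation P = (sigma/3)·ln(1 + V_wall/V)
with stretch lambda = (V/V_ref)^(1/3) and a clipped linear length
dependence h(lambda) = 1 + 2.3(lambda − 1) on active stress.  V_wall is
surface area × 2 mm.

Circulation: constant pulmonary venous pressure through a resistance (no
valve — atrial contraction refluxes into the veins, producing the booster
pressure upstroke), regularized-diode mitral valve into a time-varying
elastance LV, aortic diode into a two-element windkessel.  All lumped
parameters are this package's own choices (the study used CircAdapt
defaults it does not reprint), set once to physiological values: r_pv 80,
r_mv 20, r_ao 10, r_sys 1000 mmHg·ms/mL; c_art 1.5 mL/mmHg; LV elastance
0.05–2.5 mmHg/mL with a sin² systole of 400 ms starting 160 ms after the
atrial stimulus; V_ref = EDV/1.55 so that the passive curve carries
diastolic pressures near the prescribed 10 mmHg initial condition.  Ten
1 Hz cycles at dt = 0.5 ms (Heun) start from the passive volume at
10 mmHg; the 9th→10th cycle differences are ~0.1 % (well under the 2 %
convergence criterion), and per-cycle mass balance closes to machine
precision.

Baseline calibration adjusts the tension gain and pulmonary pressure by
damped multiplicative fixed-point until the active emptying fraction is
30 ± 2 % and the pre-contraction volume matches the descriptor EDV within
2 %.  The calibrated gain and circulation are then frozen for all design
runs of that patient/burden.

Known limitations inherited from the reduction: conduit function is low
(as in the source study), there is no atrioventricular plane traction, no
pericardial constraint, no fluid–structure interaction, and spatial
heterogeneity only enters through the compartment fractions and the
activation delay.

## PV metrics

Landmarks: volume/pressure at the stimulus (LAVpreA, LAPpreA), cycle
extremes (LAVmin, LAVmax), and the maximal A-loop pressure (LAPmaxA).
Metrics: A-loop area by the shoelace formula (reported in mJ;
1 mmHg·mL = 0.1333 mJ), booster (LAVpreA−LAVmin)/LAVpreA, reservoir
(LAVmax−LAVmin)/LAVmin, conduit (LAVmax−LAVpreA)/LAVmax, upstroke
(LAPmaxA−LAPpreA)/LAPpreA; total/active/passive emptying fractions follow.
The A-loop is segmented from the stimulus to the first self-intersection
of the PV path after minimum volume, closed at the intersection point; if
no intersection occurs within the cycle it closes where volume recovers
its pre-stimulus level.  The rule is stable under resampling and the area
uses the absolute value, so traversal direction and start index are
irrelevant.

## Sensitivity designs and statistics

OFAT: baseline plus nine single-F runs.  FFD: the 2^(9−5) table stored as
literal data (32 columns; combination 32 fully fibrotic), guarded by a
checksum and balance tests (16 F per factor, 8 runs per pairwise level
cell).  Metrics are normalized per patient by that patient's baseline
before pooling.  Main effects compare F vs B groups per factor:
mean(F)/mean(B) − 1, two-sample t-test, Anderson–Darling normality flag at
the 5 % level; no multiple-testing correction is applied (matching the
source analysis; the report carries the comparison count implicitly in its
rows).  The pairwise interaction coefficient is
arcsin((FB·BF − FF·BB)/(‖[FB,FF]‖·‖[BB,BF]‖)) on the four group means;
its numerator — hence the synergy/mitigation sign — is exactly symmetric
under factor swap, while the printed normalization is not, so the matrix
is built by evaluating each unordered pair once.  An interaction-plot
line-direction variant is available behind a `convention` switch.

With identity responses the estimator is exact: a planted single-factor
multiplicative effect is recovered to 1e-12, and additively separable
increments are recovered exactly by the group-mean difference (pairwise
balance); for jointly multiplicative responses the ratio estimator carries
a small aliasing bias intrinsic to the fractional design.

## Problem sizes and runtime

Defaults were chosen so the full study (3 patients × (OFAT 10 + FFD 32)
runs × 2 burden levels, with the 8 cached cell configurations, cable
tuning and stiffness calibration) completes in a few minutes on one CPU:
surfaces at 1.5 mm target edge length (~20k triangles, ~18k eligible),
cell model at dt 0.025 ms for 50 beats, cable at 0.1 mm/20 mm, chamber at
dt 0.5 ms for 10 cycles.  All generators and the pipeline are deterministic
under a fixed seed.
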