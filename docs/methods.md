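# Methods

`kneeplan` simulates unloaded knee extension of pre-diseased and
implanted knee models and optimizes the position of total-knee
components so that post-operative kinematic and ligament-strain curves
reproduce the pre-diseased ones.  This note documents the model, its
assumptions, the numerical choices, and what the synthetic patients do
and do not represent.

## Joint kinematics

Tibiofemoral motion is described in the Grood–Suntay joint coordinate
system.  For a right knee with anatomical frames (x anterior, y
proximal, z lateral), the flexion–extension axis is fixed to the femur
(z), the external–internal axis to the tibia (y), and varus–valgus is
carried by the floating axis; the rotation is the intrinsic Z–X–Y Euler
sequence with angles (−FE, VV, −EI), singular at VV = ±90°, far outside
the working range.  Translations are resolved along the classic
non-orthogonal triad (e1 femoral z for LM, e3 tibial y for PD, floating
e2 for AP), not projected onto either body frame; this is the cited
convention and the alternative projection was deliberately not used.
Positive values are anterior, lateral, proximal, external, varus.  Left
knees are handled by mirroring at input: the sagittal mirror negates
LM, VV, EI and preserves FE, AP, PD, which the tests verify.

## Ligaments

Eight bundles are modelled (ACL, PCL, dMCL, sMCL, LCL, ALL, OPL, PC),
one straight line element per named structure, because the analysis
reports one strain curve per structure.  Wrapping is ignored; the
surrogate's slack-length calibration absorbs the resulting length
offsets.  The constitutive law is the standard quadratic-toe/linear
spring in engineering strain ε = (L − L0)/L0:

    f(ε) = 0                          ε ≤ 0
    f(ε) = k ε² / (4 εl)              0 < ε ≤ 2 εl
    f(ε) = k (ε − εl)                 ε > 2 εl

with toe limit εl = 0.03 and linear-region stiffness k of order
1000–9000 N per unit strain, the magnitudes in common use for this
ligament set.  The law is C¹ at the transition and tension is never
negative.  Slack lengths are calibrated from per-bundle reference
strains at the **zero joint-coordinate pose at full extension**; the
equilibrium pose at 0° itself depends on L0, so calibrating at the zero
pose breaks that circularity with a deterministic convention.  The
reference strains (≈ 1.5–2.5 % at extension, PCL slack at −2 %) are
generator defaults chosen once so that simulated pre-diseased peak
strains fall in the few-percent range expected for passive flexion;
they are frozen in the repository and not re-fitted per run.

Ligament pretension matters structurally: it is what holds the
articular surfaces in compression (net ligament compression well above
the ~39 N gravitational distraction of the hanging shank), and that
compression is the path through which implant position influences
kinematics and strains.

## Contact surrogate

The articular surfaces are an analytic surrogate, not meshes: one
sphere per femoral condyle (single sagittal radius, congruent with a
single-radius implant design) articulating on a dished second-order
tibial profile per compartment,

    y(x, z) = y0 + s·x + a_x (x − x_c)² + a_z (z − z_c)²,

where s = tan(slope) encodes posterior tibial slope.  Near contact the
sphere is represented by its osculating paraboloid, which makes the gap
function quadratic and separable; the minimum gap, contact point and
normal then have closed forms (valid while the dish curvature stays
below the sphere curvature, which the constructor enforces).  The
pressure law is elastic-foundation-like, F = K·d^p with exponent p = 2
and K = 300–400 N/mm², giving sub-millimetre penetrations under
physiologic loads.  Contact force is continuous at first touch and the
energy K·d^(p+1)/(p+1) is C¹, which the equilibrium solver relies on.
The surrogate reproduces the qualitative couplings that drive the
optimization — slope shifts the AP equilibrium anteriorly, joint-line
proximalization slackens the envelope, dish curvature steers rotations —
without claiming mesh-level fidelity.

## Quasi-static extension trial

Flexion is prescribed by a motion driver from 60° to 0° on a uniform
grid of t = 60 samples inclusive of both endpoints (step 60/59); the
quadriceps is not modelled as a separate actuator because with flexion
prescribed in an unloaded trial its action is absorbed by the driver's
reaction moment.  At each sample the five free coordinates (AP, LM, PD,
EI, VV) minimize the total potential (ligament strain energy + contact
energy + gravity, gravity acting along −y of the femoral frame on the
4 kg shank, centre of mass 250 mm distal).

The equilibrium residual is defined as the Euclidean norm of the five
generalized forces with the two moment components converted to force
units by a 40 mm lever arm; a converged sample must be below 5 N.  The
norm choice and lever arm are exposed in `SolverSettings` because the
contract does not itself fix them.  Internally each step is solved far
tighter than the contract (≈10⁻⁸ N) by a damped Newton iteration on the
analytic potential gradient: the previous flexion step's Hessian (finite
differences of the analytic gradient, BFGS-updated between refreshes)
preconditions the next step, a floating-point-aware Armijo line search
guards descent, and a gradient-only Newton polish finishes each step
because energy differences saturate machine precision long before the
gradient does.  An L-BFGS-B energy minimization acts as a rescue path;
a step that still misses the contract is flagged in the trace (feeding
the optimization penalty) rather than aborting the simulation.  Warm-
and cold-started solves agree to better than 10⁻⁶, and halving the
flexion step changes nothing beyond solver tolerance — the trial is
genuinely quasi-static.

## Implantation and placement parameters

The mechanical-alignment (MA) baseline replaces the native surfaces
with the implant surrogate at neutral alignment: zero tibial slope,
neutral EI/VV, joint line restored (insert thickness, default 9 mm,
matches the composite resection), condylar spheres kept congruent with
the native ones, ACL removed (cruciate-retaining design), all other
ligaments untouched.

The placement vector x has nine components relative to MA: femoral
AP/LM/PD translations and FE/EI/VV rotations, tibial FE/EI/VV rotations
(tibial translations are structurally fixed).  Component sign
convention: positive = posterior/medial/proximal translation and
flexion/internal/varus rotation — deliberately different from the
kinematic reporting convention, with explicit converters at the
interface.  Positive tibial FE adds posterior slope.  Rotations apply
in the intrinsic order FE → EI → VV about the component frame (origin
at the joint-line centre); the order is a fixed, documented choice, as
is rotating about the component rather than the anatomical frame.
Default bounds: ±6 mm and ±6°, femoral FE narrowed to ±3° as a proxy
for the anterior-notching constraint (no geometric notching
computation).  One surrogate component size is modelled; sizing is a
clinical step outside scope.

## Objectives and optimization

The objective is Σᵢ wᵢ (1/t) Σθ (yᵢ,θ(x) − yᵢ,θ^ref)² + P over the
flexion grid, with variables drawn from the five kinematic coordinates
and the seven retained-ligament strains (strains enter unitless; the
ACL, resected at implantation, is excluded from strain objectives but
still reported pre-operatively).  A penalty of 10³ is added once per
triggered condition class per evaluation — once if any sample exceeds
the 5 N residual contract, and (peak-constrained target) once if any
strain sample exceeds that ligament's pre-diseased peak.  "Once per
class" rather than per sample is a documented reading of the penalty's
definition and is exposed on the `ObjectiveSpec` object.

Five surgical targets instantiate the weights: ST1 kinematics only,
ST2 strains only, ST3 strains with 8× weight on sMCL, dMCL and LCL
(the named collateral structures; the ALL is not included in the 8×
set), ST4 strains plus the peak penalty, ST5 all twelve variables with
each block rescaled so kinematics and strains contribute exactly 0.5
each at the MA baseline (per-block, not per-variable, equalization).

The search runs CMA-ES — implemented in-package following the standard
(μ/μ_w, λ) formulation with cumulative step-size adaptation and
rank-one + rank-μ covariance updates — in bound-normalized [−1, 1]
coordinates: population 16, initial step 0.25 of the half-width, start
at MA (x = 0, always evaluated so the best solution can never be worse
than MA), box constraints by repair with a quadratic distance penalty,
termination on budget, target value, step-size collapse or stagnation.
Every evaluated candidate is recorded as the solution space.  Among
candidates within 5 % of the best objective, `select_clinical` returns
the one minimizing the root-sum-square of bound-normalized parameters —
a scalar deviation-from-MA norm that makes millimetres and degrees
commensurate; ties break by evaluation order.

## Synthetic patients and hidden truth

The generator replaces the clinical imaging pipeline (CT segmentation,
statistical shape models, cadaver-to-patient morphing): it emits knee
models with plausible adult geometry (condylar spacing 44 mm, joint
line 21.5 mm distal to the transepicondylar origin, native posterior
slope defaulting to 5°), attachment sites jittered per patient (0.35 mm
s.d.), and femoral attachment points tuned once, with the equilibrium
simulation in the loop, so that every strain curve stays within a
(−5 %, +12 %) plausibility envelope over the arc while showing the
expected patterns (posterior structures taut in extension, PCL engaging
in flexion, near-isometric collaterals).  What the generator does *not*
emulate: real articular geometry variation, osteophytes, cartilage
thickness maps, menisci, patellofemoral mechanics, or diseased soft
tissue.  Passing tests therefore demonstrate the *method* — simulation,
objectives, search, selection — not clinical accuracy on real patients.

Hidden-truth scenarios take the reference curves from the implanted
model simulated at a known x\* strictly inside the bounds, so the
global minimum is zero at x\* by construction and optimizer acceptance
is uncontaminated by surrogate-model mismatch.  The realistic mode —
optimizing against the native-surface pre-diseased trace, as a surgeon
would — is also exercised; there zero objective is unattainable because
implant and native geometries differ.  Note that the extension trial
senses some placement directions only weakly (femoral EI most
notably), so hidden-truth recovery is asserted on the objective value,
not on every parameter.

## Reporting

Curve agreement is summarized as RMSD over the flexion arc, per
variable; translations as mean ± sample (n−1) standard deviation over
{AP, LM, PD}, rotations over {EI, VV} (FE is driven and excluded).
With n = 3 and n = 2 the ddof convention visibly matters, hence it is
fixed and documented.  Strain RMSDs are reported in percent.  Percent
reduction is 100·(baseline − optimized)/baseline, displayed at one
decimal.

## Problem sizes and defaults

Default runs use the 60-sample grid throughout.  The acceptance script
runs the surgical-target optimizations at a 700-evaluation budget with
early stagnation stopping, and the hidden-truth recovery at up to 2000
evaluations with a target of 10⁻³ of the MA objective; these sizes give
stable, reproducible summaries for a single-process run while
exercising the full pipeline.

## Known limitations

* The contact surrogate is analytic; absolute kinematic magnitudes
  depend on its curvatures and are not patient-accurate.
* Single-bundle ligaments without wrapping understate strain gradients
  across broad structures (sMCL, PC).
* The unloaded extension trial senses some placement parameters weakly;
  conclusions about those parameters' clinical effect would need loaded
  activities.
* One implant size and one (right-knee) side are modelled.
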