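# Methods

## Cell model

The myocyte is the O'Hara–Rudy dynamics (ORd) human ventricular model
with its published ENDO/MID/EPI parameter variants, except that the fast
sodium current is the ten Tusscher (TNNP06) formulation (gates m, h, j;
G_Na = 14.838 mS/µF).  The substitution is standard practice when the
model is coupled into tissue: the original ORd I_Na produces
unphysiologically slow conduction.  Because the ORd CaMK pathway acts on
its own I_Na gates, CaMK modulation of I_Na is dropped together with the
substitution; CaMK effects on I_NaL, I_CaL, Jrel and Jup are retained.
The state vector has 38 entries (Vm, 8 ion concentrations, 25 gating /
relaxation variables, the L-type `nca` fraction, two SR-release fluxes,
CaMK-trapped fraction).

Nine currents are scalable by multiplicative factors (I_Na, I_NaL, I_CaL,
I_to, I_Kr, I_Ks, I_K1, I_NaCa, I_NaK).  Factors scale the maximal
conductance/permeability (for I_NaCa and I_NaK, the overall turnover
magnitude; for I_CaL, the whole L-type flux including its Na⁺/K⁺
components).  A factor of 1 is exactly the unmodified model; simulations
with an all-ones factor set are bit-identical to factor-free runs.

### Numerics

Operator-split fixed-step integration: Rush–Larsen exponential updates
for every gating/relaxation variable, forward Euler for Vm, ion
concentrations and CaMK.  Default dt = 0.005 ms; halving dt changes a
paced APD90 by < 0.2 ms and the upstroke peak by < 1 mV.  The GHK-type
driving forces guard the removable singularity at Vm = 0 by clamping the
normalized voltage at 10⁻⁸.  Non-finite states abort the run with the
failing step (and node, in tissue).

### Initial conditions and pacing

`init_state` returns quiescent equilibria of this model, precomputed by
integrating each unstimulated cell type for 500 s and frozen in
`data/ord_rest_states.json` (regenerable with `ord.equilibrate_rest`).
The shipped rest states drift < 0.01 mV over 10 s.  The cell stimulus is
−80 µA/µF for 0.5 ms (≈2× diastolic threshold; configurable).  Steady
pacing is reported against the consecutive-beat criterion |ΔAPD90| < 1 ms;
100 beats at BCL 1000 ms satisfy it for all three cell types.

## Pharmacology

Pore-block theory: blocked fraction θ(D) = 1/(1+(IC50/D)^nH), remaining
conductance f = 1 − θ.  Activators: f(D) = 1 + (Act_max−1)/(1+(EC50/D)^nH),
i.e. the EC50 marks half of the *span* (f = 1 + (Act_max−1)/2), matching
the functional form used for the reference I_Kr activator; f(0) = 1 by
the limit, avoiding the 0⁰ division.  Factor sets compose per-channel
multiplicatively; composition is commutative and associative, and
disease remodeling uses the same currency.

Hill fitting is ordinary least squares (`scipy.optimize.curve_fit`) with
deterministic initialization: IC50/EC50 at the geometric mean of the dose
range, nH = 1, Act_max at the maximum observed response.  Block fits need
≥ 3 points (2 parameters), activation fits ≥ 4 (3 parameters).
Noise-free synthetic curves are recovered to numerical precision; at 1%
Gaussian response noise over 8 log-spaced doses, parameters are recovered
within 10%.

The bundled library (data/drugs.yaml) carries the per-channel Hill
parameters, provenance notes (expression system/species) and dose plans
for ranolazine, HW-0168, amiodarone, verapamil, nifedipine, quinidine,
vanoxerine, bepridil, KB130015, ICA-105574, NS1643 and NS3623.  Two
published inconsistencies are resolved as follows: the ranolazine I_Kr
entry (IC50 12 µM, nH 1) is applied to I_Kr (its equation label in the
source misprints the channel); NS1643's Act_max is taken from the
parameter table (1.5) rather than the footnote's 152%.  Amiodarone's
I_NaK and I_NaCa entries are applied at all doses.

## Disease remodeling placeholders

The measured CO/CORM-2 and heart-failure remodeling magnitudes are not
publicly deposited, so `data/remodeling_placeholder.yaml` ships
synthetic, loudly flagged stand-ins that are qualitatively correct in
direction (CO: I_NaL ×2.0, I_Na ×0.9, I_CaL ×0.95, I_K1 ×0.9, I_Kr
×0.55; HF: reduced I_to/I_Ks/I_K1/I_NaK, raised I_NaL/I_NaCa; HF+CO is
their product).  Magnitudes were set once so that the composed HF+CO MID
cell reproduces the qualitative disease phenomenology — markedly
prolonged APD with 2:1 alternating EADs, while HF alone stays EAD-free
and healthy+CO prolongs APD without EADs.  Every quantitative output
under these conditions therefore characterizes the machinery, not
measured biology, and passing tests say nothing about real CO exposure
magnitudes.  Gating-kinetics remodeling is not expressible in the
conductance-factor currency and is out of scope until measured values are
supplied.

## 1D strand

Monodomain cable with second-order central differences, mirror (no-flux)
boundaries, forward Euler, same dt as the cell.  Default geometry: 100
nodes, dx = 0.15 mm (15 mm), 25:35:40 ENDO:MID:EPI from the paced ENDO
end, D = 0.127 mm²/ms.  The stability number D·dt/dx² ≈ 0.028 is far
inside the explicit limit.  Pacing applies the stimulus to the first 3
nodes for 1.0 ms (tissue capture needs a longer pulse than the
single-cell 0.5 ms against the diffusive load; both configurable).  Node
initial states come from single-cell steady pacing per (cell type, factor
set) group — a cheap surrogate for long tissue pre-pacing — followed by
the configured tissue beats (default 5).

Measured planar CV between the 30% and 70% positions (activation = instant
of maximum dV/dt) is 71–72 cm/s at D = 0.127 mm²/ms.  Halving dx raises
CV by ≈ 3.9% (first-order discretization error at dx = 0.15 mm); the
surrogate cable converges to ≈ 0.1%.  A homogeneous cable at
D = 0.154 mm²/ms conducts at ≈ 80 cm/s, consistent with √D scaling; a
2D slice with distributed endocardial pacing produces lower effective
velocities, which a planar cable intentionally does not emulate.

Centering of an affected block of N nodes in a homogeneous strand puts
the extra unaffected node (odd remainders) on the low-index side, i.e.
the block occupies `[(n−N+1)//2, (n−N+1)//2 + N)`.

## Pseudo-ECG and biomarkers

φ_e is the discrete unipolar integral with central spatial gradients and
the analytic ∇(1/r); electrode 20 mm beyond the distal (EPI) end on the
axis, strand radius a = 1.1 mm.  φ_e is in arbitrary units — biomarkers
are insensitive to a, and amplitude rescaling leaves QT unchanged.

* APD_level: maximum-upstroke instant to the interpolated downward
  crossing of rest + (1−level/100)·amplitude; upstroke threshold
  10 mV/ms.
* QT: baseline = mean φ_e over the 20 ms before the stimulus; QRS onset =
  first |φ_e − baseline| above 5% of peak |QRS|; T wave = largest
  deflection after the 80 ms QRS window, validated against 1% of the QRS
  peak; T end = first return of the descending limb to within 2% of the
  T amplitude of baseline.  Failure to return before the trace ends is
  flagged as repolarization failure rather than silently truncated.
* EADs: a local minimum during repolarization followed by a rebound of
  ≥ 2 mV with the minimum above −40 mV (both configurable); per-beat
  counts are labeled none / n:1 / 1:1 / irregular.

## Protocols

* **CV restitution**: BCL from 3000 ms downward, beat-by-beat pacing per
  BCL until CV changes < 0.5% between consecutive beats (cap 20), state
  carried across BCLs; the first conduction failure terminates the curve.
* **Vulnerable window**: S1 planar wave, then a local S2 at the tested
  node over scanned coupling intervals (1 ms default step).  Outcomes are
  classified by fresh post-S2 activations at probe nodes ±10 nodes:
  none = blocked, one side = unidirectional, both = bidirectional; the VW
  is the contiguous unidirectional band.  The S2 is stronger and longer
  than the S1 stimulus (2× amplitude for the ionic model) because a
  single-node stimulus otherwise cannot capture against the diffusive
  sink.
* **Critical cell number**: centered EAD-prone block grown until a
  propagated ectopic beat appears — defined as ≥ 90% of all nodes
  activating a second time outside the pacing stimulus.  Linear scan (as
  in the source protocol) and bisection agree, and the threshold is
  verified monotone at ±1.
* **Population of models**: per-variant i.i.d. normal factors
  (mean 1.0, sd 0.2) on the nine currents, negatives redrawn (truncation
  probability ≈ 3×10⁻⁷, immaterial; per-channel Shapiro–Wilk normality
  holds at n = 1000, α = 10⁻³).  `run_population` paces each variant with
  the condition factors composed in and reports APD90, EAD flags and the
  EAD fraction; numerical failures are excluded with a count.

## Surrogate excitable model

Protocol *logic* is exercised on a two-variable Aliev–Panfilov cell
(mapped to mV, APD ≈ 355 ms) rather than the full ionic model, keeping
the vulnerable-window and critical-mass tests in seconds.  Its EAD
forcing re-injects a depolarizing current at a fixed delay after each
affected node's activation and slows those nodes' recovery so that the
forced depolarization meets recovered neighbours — reproducing the
source–sink mechanism (no propagation below a critical block size,
propagation above it; stronger drive lowers the threshold) without
claiming ventricular quantities.  Full-ionic-model runs use the same
protocol code paths.

## Synthetic fixtures

Parametric APs hit their APD90 target within one sample by construction
(linear or exponential repolarization with closed-form 90% crossings);
injected EAD bumps must out-slope the repolarization ramp to register as
true secondary depolarizations (≈10 mV Gaussian bumps at mid-AP do).
Strand activation fields snap the sample interval to an integer divisor
of the per-node conduction delay so the measured CV equals the target
exactly.  Hill datasets add seeded Gaussian noise to evaluator-generated
curves.  All fixtures are seed-reproducible.  What these fixtures do not
emulate: stochastic channel gating, beat-to-beat variability, fibrotic
heterogeneity, and measured disease magnitudes — tests passing on them
validate the measurement and protocol machinery, not clinical claims.

## Problem sizes in the test suite

Tissue runs in the suite use 50 single-cell pre-pacing beats and 2 tissue
beats (CV is insensitive to further pre-pacing); the acceptance script
uses the full 100-beat initialization and 3 tissue beats.  Population
checks pace 8–12 variants for 2–3 beats; distribution moments are checked
at the full n = 1000 (sampling is cheap).  These sizes are the package's
own defaults for a laptop-scale run; all are parameters.

## Known limitations

* Supra-threshold behavior is validated against published qualitative
  ORd behavior (resting Vm ≈ −88 mV, MID > ENDO > EPI APD90, ~70 cm/s
  planar CV) rather than a line-by-line trace comparison with the
  original code.
* No state-dependent drug binding, trapping kinetics or temperature
  correction; fixed effective concentrations only.
* 1D monodomain only — no anisotropy, bidomain effects or realistic 2D/3D
  geometry; QT rate correction (QTc) is out of scope.
* The disease-remodeling placeholders are synthetic (see above).
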