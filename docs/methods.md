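# Methods

This note documents the models, the synthetic-cohort design, the numerical
choices, and what the desk-scale studies do and do not demonstrate.

## Tissue model

We solve the anisotropic monodomain equation

    chi C_m dV/dt = div(sigma grad V) - chi I_ion + I_stim

with a transversely isotropic conductivity tensor per element,
`sigma = sigma_f f f^T + sigma_c (I - f f^T)`, where `f` is the unit fiber
direction.  Units are fixed package-wide: lengths in cm, time in ms,
voltage in mV, conductivity in mS/cm (so `sigma / (chi C_m)` is a diffusion
coefficient in cm²/ms).

Tissue classes:

- **Healthy** myocardium: baseline parameters.
- **Border zone (BZ)**: conductivity scaled by `bz_conductivity_scale`
  (default 0.4) and a remodeled cell-parameter set (below).
- **Scar**: non-excitable — scar elements are excluded from assembly
  entirely (zero conductivity, no reaction), so scar-interior nodes stay at
  the resting potential by construction.

### Cell model

The reaction term is the two-variable Mitchell–Schaeffer model,

    du/dt = h u^2 (1-u)/tau_in - u/tau_out + J_stim
    dh/dt = (1-h)/tau_open  if u < u_gate,  else  -h/tau_close

with the normalized state mapped to voltage as V = V_rest + A·u
(V_rest = −85 mV, A = 120 mV).  The mapping makes the −20 mV activation
and −70 mV repolarization thresholds meaningful.  Defaults (ms):

| parameter | healthy | BZ    | why |
|-----------|---------|-------|-----|
| tau_in    | 0.3     | 0.45  | reduced excitability; slows BZ conduction by ~√1.5 on top of the conductivity scaling |
| tau_out   | 6.0     | 6.5   | keeps the BZ action potential prolonged despite the larger tau_in (the minimum gate value is 4·tau_in/tau_out) |
| tau_open  | 120     | 120   | recovery kinetics; not exercised by single-beat studies |
| tau_close | 100     | 130   | action-potential-duration prolongation |
| u_gate    | 0.13    | 0.13  | |

The resulting action potential durations at the −70 mV return are ≈198 ms
(healthy) and ≈210 ms (BZ), i.e. a modest APD prolongation.  During design
we found that a *strong* APD step across a thin shell-shaped BZ reverses
the near-vs-far pacing effect the robustness study tests (see "Synthetic
cohort" below), because on the side of the scar facing a distant pacing
site the activation-time and APD gradients add, while for adjacent pacing
they cancel.  The defaults therefore combine the prescribed remodeling
directions (slower closing, reduced excitability) at a magnitude where
conduction slowing, not APD dispersion, carries the effect.  The cell
interface is pluggable, so a full ionic model can replace the surrogate
without touching the tissue solver.

Per-node cell parameters are volume-weighted averages over the adjacent
non-scar elements, which smooths the healthy/BZ transition over roughly
one element layer (a deliberate, resolution-consistent choice).

### Discretization

P1 (linear) tetrahedral finite elements with a lumped mass matrix;
operator splitting per time step: an explicit (forward-Euler) reaction
substep, then a backward-Euler diffusion solve

    (M/dt + K/(chi C_m)) u_{n+1} = (M/dt) u*

The system matrix is symmetric positive definite and constant in time; it
is solved with Jacobi-preconditioned conjugate gradients warm-started from
the previous step (relative tolerance 1e-10, so the iteration count — a
handful per step — does not affect the physics).  The diffusion step is
unconditionally stable; dt (default 0.1 ms, 0.05 ms in the convergence
study, 0.025 ms for CV calibration) is limited by reaction stiffness.
Everything is deterministic: identical inputs give bitwise-identical
voltage traces.

Stimuli are balls of nodes receiving a constant du/dt increment (default
1/ms for 2 ms) — adequate for a phenomenological reaction term.  Runs with
`stop_when_repolarized` end as soon as every node has returned below
−75 mV after excitation, which shortens single-beat runs without touching
any recorded quantity (all threshold crossings happen earlier).

### Conduction-velocity calibration

Planar CV is measured on a homogeneous fiber-aligned slab (1 × 0.1 ×
0.1 cm at 0.02 cm edge length) between probe planes at 25% and 75% of the
length, excluding stimulus and boundary transients.  The default
`sigma_f = 5.37 mS/cm` yields 66.0 cm/s, the baseline CV of the robustness
study; the default anisotropy ratio `sigma_f/sigma_c = 4` gives a
cross-fiber CV of ≈33 cm/s (CV scales with the square root of
conductivity).  `tune_conductivity_to_cv` inverts the square-root law as a
fixed-point iteration (sigma ← sigma·(target/measured)²) verified by
re-simulation, scaling both conductivities by the same factor so the
anisotropy ratio is preserved exactly.

## Synthetic cohort

Image-derived ventricular cohorts are external data; the generator
replaces them with analytic slabs in which every label has a closed-form
ground truth:

- a box `[0,Lx]×[0,Ly]×[0,Lz]` with `Lz` the wall thickness and z the
  transmural direction;
- a spherical scar core, a concentric BZ shell of width `bz_thickness`
  (element classification by centroid);
- rule-based fibers: in-plane unit vectors whose angle rotates linearly
  with normalized transmural depth from the endocardial to the epicardial
  angle (default −60°→+60°);
- structured tetrahedralization: a regular hexahedral grid, each cell split
  into six tetrahedra sharing its main diagonal (Kuhn subdivision —
  conforming without orientation flips).  The grid spacing is
  `target_edge_length / 1.2821`, where 1.2821 is the exact mean unique-edge
  length of that subdivision, so the generated mean edge length matches the
  requested one.

Per-patient geometry is drawn uniformly from configured ranges; one master
`SeedSequence` spawns a child per patient, so a whole cohort is
reproducible from one integer.

Distances to tissue-region surfaces ("within 1 cm of scar", pacing-site
placement, BZ contraction/expansion) are exact Euclidean point-to-triangle
distances to the faceted region boundary (KD-tree candidate prefiltering
with a certified exactness bound and brute-force fallback).  Geodesic
distances are deliberately not used: the volumetric "within d of scar"
constructions are Euclidean by definition and oracle-checkable.

### Study 1 conditions (verification)

Three synthetic patients (slabs ≈1.2 × 1.0 × 0.42 cm, scar radius
0.10–0.12 cm, BZ 0.05–0.07 cm), mesh families at mean edge lengths
0.10 / 0.05 / 0.025 cm — mirroring the ~1030→275 µm span of full-scale
resolution studies, with the finest member as ground truth.  Apical-pacing
analogue: a stimulus at the x=0 face center; base probe at the opposite
face; "V1-like" electrode 4 cm from the domain centroid along +x.  Runs
last 45 ms at dt = 0.05 ms (activation and ECG only; the convergence
metrics do not need repolarization), dt held fixed across resolutions so
the study isolates spatial error.

### Study 2 conditions (uncertainty quantification)

Five synthetic patients: long slabs ≈6 × 1.2 × 0.7 cm with the scar at
x = 1 cm (radius 0.14–0.17 cm) and BZ shells of 0.12–0.16 cm — within the
spread of measured BZ thicknesses (≈1.2 ± 1.3 mm average across hearts)
and thick enough that a 0.5 mm contraction leaves a non-empty BZ at the
0.12 cm mesh resolution.  Pacing sites are selected at 0.2 cm and 4.5 cm
from the scar surface (lowest node index within tolerance); the slab
geometry makes the near site transmurally/cross-fiber adjacent to the scar
while the far site lies along the fiber axis.  Single resolution
(0.12 cm), one beat of 420 ms at dt = 0.1 ms with early stop.

**How the near>far effect arises.** Pacing adjacent to the scar sends a
strongly curved, slowly expanding wavefront through the cross-fiber and
BZ tissue inside the 1-cm scar neighborhood; wavefront curvature and the
reduced BZ conductivity/excitability depress the local CV, and the
repolarization-gradient magnitude tracks 1/CV.  Pacing 4.5 cm away sends
an essentially planar wave along the fast fiber axis through the same
neighborhood.  With the modest BZ APD prolongation above, this conduction
asymmetry dominates and every synthetic patient shows a higher HRGV for
near pacing — the cohort-level conclusion whose robustness the scenario
battery then interrogates.  This is a designed property of the synthetic
electrophysiology: passing the battery demonstrates that the *machinery*
(perturbation, sampling, statistics) behaves correctly on a cohort that
genuinely carries the effect, not that real hearts do.

## Statistics

- One-sided paired t-test: t = mean(d)/(sd(d)/√K), d = near − far, sample
  (K−1) SD, upper-tail p from Student's t with K−1 df.  Zero-variance
  differences are degenerate; the documented convention reports p = 0 /
  0.5 / 1 by the sign of mean(d) with a flag.
- Scenario battery (8 entries): BZ input — contracted systematic, expanded
  systematic, worst-case (per-patient max near vs min far; recorded with
  the caveat that a paired t statistic is not monotone in per-patient
  differences, so the "bounds all assignments" interpretation is
  heuristic), and discrete Monte-Carlo; conductivity input — low/high
  systematic, discrete Monte-Carlo, and continuous CV ~ N(66, 6.6²) cm/s
  sampling with per-patient piecewise-linear HRGV interpolation, draws
  clamped to the simulated CV range (no extrapolation beyond simulated
  physics).
- Monte-Carlo samplers draw one variant per patient per sample (the same
  variant supplies both pacing sites), uniformly and independently;
  fractions significant are reported with n_samples and seed.  The desk
  default is 10^4 samples (10^6 by flag); for K ≤ 6 the samplers are
  validated against exhaustive enumeration of all 3^K assignments.

## Numerical choices and degenerate inputs

- Threshold crossings are linearly interpolated between output samples, so
  activation/repolarization times are first-order independent of the
  output interval.  Unactivated/unrepolarized nodes carry NaN sentinels;
  elements with any NaN corner are excluded from gradient statistics.
- The repolarization gradient is the exact P1 gradient — exact to machine
  precision for nodal fields linear in space.
- The pseudo-ECG uses single centroid quadrature, per-element constant
  gradients, and k = 1 (arbitrary units); relative error and lag are
  invariant to k.  Electrodes inside (or within one edge length of) the
  mesh are rejected.
- Cross-correlation lag uses un-normalized zero-padded dot products; ties
  break toward the smallest |shift|, then the negative shift.
- COV cells with zero mean (common for the integer-valued ECG lag at fine
  resolutions) are reported as NaN, not zero.
- BZ contraction/expansion measure centroid-to-interface-surface distances
  (BZ–healthy interface for contraction; boundary of BZ ∪ scar for
  expansion); scar labels are never altered.  Perturbation operators are
  pure functions.

## Limitations

- The synthetic slabs have no chamber anatomy, no transmural cell-type
  heterogeneity, no torso conduction model (electrodes are explicit
  coordinates), and scars are spheres; conclusions about *real* cohorts
  require the external imaging-derived meshes the pipeline also accepts
  (labeled .vtu input).
- The phenomenological cell surrogate reproduces activation/repolarization
  structure, not ionic detail; absolute HRGV magnitudes are not
  physiological predictions.
- The desk-scale sample sizes (3 and 5 patients, 10^4 MC samples) exercise
  every code path at full fidelity but have less statistical resolution
  than a 24-patient, 10^6-sample study; all sizes are configuration knobs.
- Only spatial discretization error is studied (dt fixed); Richardson-type
  error estimation is out of scope.
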