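# psmcred

Credibility evidence for **patient-specific cardiac electrophysiology
models** deployed as virtual cohorts: a tested pipeline for the two
simulation studies that underpin verification and uncertainty
quantification (VVUQ) of such cohorts —

1. **Multi-patient mesh-convergence study** (verification): how much does
   spatial-discretization error vary *across patients*?
2. **Robustness study** (uncertainty quantification): does a cohort-level
   scientific conclusion survive plausible errors in a personalized input
   (infarct border-zone extent) and a non-personalized input (tissue
   conductivity)?

The package is aimed at computational cardiac-EP groups who need these
analyses to be reproducible and unit-tested rather than one-off scripts.
Because the image-derived ventricular cohorts such studies normally use are
external data, `psmcred` ships a **synthetic cohort generator**: analytic
myocardial slabs with an embedded spherical scar core, a surrounding
border-zone (BZ) shell of thickness comparable to measured infarct border
zones (~1 mm), transmurally rotating fibers, and nested mesh resolutions —
every label has a closed-form ground truth, so every pipeline stage is
testable end-to-end on one workstation.

## Model

Tissue electrophysiology is the anisotropic **monodomain** model

```
chi C_m dV/dt = div( sigma grad V ) - chi I_ion + I_stim ,
sigma = sigma_f f f^T + sigma_c (I - f f^T)
```

discretized with P1 finite elements (lumped mass) on labeled tetrahedral
meshes and operator splitting (explicit reaction, implicit diffusion).
Scar is non-excitable (removed from assembly); BZ elements carry scaled
conductivity and a remodeled cell-parameter set.  The reaction term is the
two-variable Mitchell–Schaeffer model with the normalized state mapped to
physical voltage (V = −85 mV + 120 mV·u), so threshold-based quantities are
meaningful: activation at the −20 mV upstroke crossing, repolarization at
the return below −70 mV.

Quantities of interest:

- normalized apex-to-base activation time (activation time at a base probe
  divided by its distance to the pacing node, ms/cm);
- pseudo-ECG at a virtual electrode,
  `phi(e) = -k ∮ (sigma grad V) · grad(1/r) dV`;
- discretization-error metrics against the finest mesh: the scaled
  infinity-norm ECG error `E_X = ||phi_X − phi_H||_inf / ||phi_H||_inf` and
  the cross-correlation lag Δt, summarized across patients by the
  coefficient of variation (sample SD / mean);
- **HRGV** (high repolarization gradient volume): the volume of healthy/BZ
  tissue within 1 cm of scar where |∇T_rep| > 30 ms/cm — a surrogate for
  pacing-induced arrhythmia risk near infarcts.

The robustness study tests the hypothesis *HRGV is greater pacing 0.2 cm
from scar than 4.5 cm from scar* (one-sided paired t-test, α = 0.01)
under: systematic BZ over-/under-segmentation (contract 0.5 mm / expand
1 mm), the worst-case max/min pairing, Monte-Carlo sampling over the 3^K
discrete variant assignments, conductivities retuned to 80%/120% of the
baseline conduction velocity (anisotropy ratio preserved), and continuous
CV ~ N(66, 6.6²) cm/s sampling with piecewise-linear HRGV interpolation.

## Worked example

```python
from psmcred import (PatientSpec, generate_patient, select_pacing_sites,
                     SimulationConfig, Stimulus, run_monodomain,
                     QoiConfig, activation_map, repolarization_map,
                     repolarization_gradient, hrgv)

spec = PatientSpec(patient_id="demo", wall_thickness=0.7,
                   domain_extent=(6.0, 1.2, 0.7),
                   scar_center=(1.0, 0.6, 0.35),
                   scar_radius=0.17, bz_thickness=0.12)
mesh = generate_patient(spec, target_edge_length=0.12)
near, far = select_pacing_sites(mesh, [0.2, 4.5])   # cm from scar surface

qoi = QoiConfig()
for name, node in [("near", near), ("far", far)]:
    cfg = SimulationConfig(duration=420.0, dt=0.1, output_interval=2.0,
                           stop_when_repolarized=True,
                           stimulus=Stimulus(center=tuple(mesh.nodes[node])))
    sol = run_monodomain(mesh, cfg)
    rep = repolarization_map(sol, qoi)
    g = repolarization_gradient(rep, mesh)
    print(name, round(hrgv(g, mesh, qoi), 4), "cm^3")
```

prints

```
near 0.0825 cm^3
far 0.04 cm^3
```

— pacing adjacent to scar roughly doubles the high-gradient volume,
because the wavefront leaves the nearby pacing site strongly curved and
crosses the slow cross-fiber/BZ tissue next to the scar, while the distant
site sends a planar wave along the fast fiber axis.  Across the 5-patient
synthetic cohort the paired test gives t = 22.99, one-sided
p = 1.1e-05 (< 0.01).

Command-line equivalents:

```bash
psmcred cohort generate -k 3 -e 0.1,0.05 -s 1 -o cohort/
psmcred study convergence -k 3 -s 1 -o results/study1/
psmcred study robustness  -k 5 -s 1 -o results/study2/
```

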