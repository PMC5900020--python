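# Methods

## Scientific setting

After myocardial infarction, a rim of surviving but remodeled myocardium —
the border zone (BZ) — surrounds the collagenous scar core. Experimentally
reported BZ changes include shorter or longer action-potential duration
(APD), slowed conduction (interstitial fibrosis reducing transverse
coupling, or near-isotropic slowing), and myofiber disarray. How each of
these representations shapes the spatial pattern of repolarization — and
hence the repolarization gradients associated with unidirectional block and
re-entry — is the question this package addresses with an idealized,
fully-controlled 2D model.

## Model

### Tissue

A 30 x 30 mm sheet of ventricular myocardium contains a central 10
mm-diameter scar core, modeled as a perfect insulator by *removing* its
elements from the mesh (the internal boundary is then no-flux by
construction). A 2 mm annulus around the core is labeled border zone.
Healthy fibers run along x; BZ fibers are horizontal or independently
uniformly random per element (fiber disarray with no correlation length).
The mesh is a structured crossed-diagonal triangulation: deterministic,
exactly mirror-symmetric about the vertical midline, with the grid pitch
chosen so the realized mean edge length equals the requested resolution
(pitch = 3/(2+sqrt(2)) x resolution).

Electrical propagation follows the monodomain model

    beta * Cm * dV/dt = div(sigma grad V) - beta * (I_ion - I_stim)

with surface-to-volume ratio beta = 0.14 um^-1, membrane capacitance Cm =
1 uF/cm^2, and elementwise bulk conductivity tensor sigma = R(theta)
diag(sigma_l, sigma_t) R(theta)^T. The effective diffusivity is D = 0.1 *
sigma / (beta * Cm) in mm^2/ms for sigma in S/m (unit audit in
`fem.py`); the normal longitudinal value 0.1890 S/m gives D = 0.135 mm^2/ms.

Conductivity sets (S/m, longitudinal / transverse):

| set                  | sigma_l | sigma_t | intent |
|----------------------|---------|---------|--------|
| normal_anisotropic   | 0.1890  | 0.0690  | healthy tissue (~0.6 / 0.4 m/s) |
| decreased_transverse | 0.1890  | 0.0069  | interstitial fibrosis (transverse 10% of normal) |
| decreased_isotropic  | 0.0689  | 0.0689  | slow isotropic conduction (~0.4 m/s) |

### Membrane

The ionic model is the 2006 ten Tusscher–Panfilov human ventricular
formulation, epicardial parameter set, transcribed from the published
reference implementation (19 state variables; analytic rapid-buffering
updates for the three Ca2+ pools). BZ electrophysiology is represented by
scaling the slow delayed-rectifier conductance g_Ks: x0.5 prolongs and x2.0
shortens the steady-state APD by roughly 40 ms at a 500 ms cycle length,
reproducing the reported BZ APD alterations. The choice of model generation
is configurable in spirit (the g_Ks scaling is the only variant knob), and
the epicardial set is the default because the idealized sheet represents an
epicardial/lateral BZ.

### Protocol

Cells are pre-paced 100 beats at a 500 ms cycle length (single-cell, 0D);
the end-diastolic state seeds every tissue node. The tissue is then paced 5
beats at the same cycle length through a 0.5 mm-radius half-disc of nodes at
the center of the bottom edge; maps are computed on the final beat.
Stimulus amplitude is twice the diastolic threshold: for single cells the
threshold is found by bisection on a trial beat; for tissue it is found once
by bisection on the normal-conductivity sheet and held identical across all
configurations.

Activation time is the first upward crossing of -20 mV after the final
stimulus onset; repolarization time the first downward crossing of -70 mV
after local activation; both linearly interpolated between output samples
(1 ms sampling bounds the crossing error at about +-0.5 ms). The
repolarization gradient is the magnitude of the spatial gradient of
repolarization time: exact per linear triangle, averaged to nodes with area
weights (exact for linear fields, zero on constants). Summary statistics
report per-region maxima and the tissue area exceeding 3.2 ms/mm (the
experimental threshold for unidirectional block) and 5 ms/mm.

## Numerics

* Operator splitting per step: ionic update (exponential Rush-Larsen gates,
  forward-Euler concentrations and V), then implicit (backward Euler)
  diffusion with a lumped mass matrix, factorized once per run (SuperLU,
  symmetric-mode minimum-degree ordering).
* Two ionic code paths: an exact transcription and a table-accelerated path
  (all purely voltage-dependent factors tabulated on a 0.05 mV grid per
  fixed dt; reversal potentials refreshed from the slowly-drifting
  concentrations every 0.5 ms). The two paths agree to ~0.02 mV over paced
  beats (the test suite asserts < 0.5 mV); tissue runs use the table path.
* Default dt = 0.02 ms (single cell, strips). Desk-scale 2D runs use a 0.1
  ms diffusion step with 0.05 ms ionic sub-steps; single-cell APD changes by
  < 0.5 ms between 0.02 and 0.05 ms sub-steps and the BZ-edge gradient
  extremum by < 1% between 0.025 and 0.05 ms sub-steps at fixed geometry.
* Problem sizes: the configuration sweep in the test suite runs at 0.30 mm
  mean edge length with 2 paced beats (the pre-paced initial state makes
  later beats nearly periodic); the headline BZ-gradient quantity and the
  acceptance script use 0.15 mm and the full 5-beat protocol; strips for CV
  use 0.1 mm. All are the same code path as the 0.05 mm full-resolution
  setting (`--paper` preset).

## Synthetic data and what the tests show

The geometry generator *is* the study's data source: an idealized disc scar
with a homogeneous annular BZ, abrupt (or optionally linearly ramped)
property transitions, and either coherent or fully uncorrelated fiber
disarray. It deliberately omits: surviving strands/isthmuses inside the
scar, 3D wall geometry and transmural fiber rotation, spatially graded
remodeling, and myofibroblast coupling. Passing tests therefore demonstrate
the mapped consequences of *idealized* BZ property assignments, not
patient-specific predictions.

## Design choices on open points

* APD convention: APD90 from the maximum-upstroke instant, with the -70 mV
  crossing also available; the two differ by < 15 ms for these cells and the
  tissue repolarization maps use the -70 mV convention.
* BZ annulus membership is half-open: centroid radius in (5, 7] mm; node
  properties by majority of incident elements.
* CV measurement: 20 x 1 mm strip, full short-edge stimulus, least-squares
  fit of activation time vs distance over the central 50% (x in [5, 15] mm),
  velocity = inverse slope. Calibration multiplies sigma by the squared
  CV ratio (cable-theory square-root law), tolerance 1%, at most 10
  iterations.
* The decreased-transverse value is fixed arithmetic (10% of normal), not
  calibration output.

## Known limitations

* With the shipped conductivities this implementation conducts somewhat
  faster than the calibrated velocities the conductivities were derived
  for: ~0.67 m/s longitudinal (vs 0.6) and ~0.11 m/s for the
  10%-transverse case (vs 0.12) at the 0.1 mm strip protocol. A
  resolution/step convergence study places the continuum longitudinal CV of
  this membrane model near 0.70 m/s at sigma_l = 0.1890 S/m, so the offset
  is a property of the model generation/solver combination, not of the
  discretization. The transverse normal velocity (0.40 m/s) and the inverse
  calibration (sigma ~ 0.069 S/m for 0.4 m/s) are reproduced closely.
* The monodomain model carries no extracellular potentials; electrogram
  features (fractionation) and bidomain effects are out of scope.
* No reduced sodium-channel availability, post-repolarization
  refractoriness, or arrhythmia-induction protocols: the package maps
  repolarization-gradient substrate, it does not simulate re-entry.
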