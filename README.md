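# bzsim

Monodomain simulation of activation and repolarization around an infarct
border zone (BZ) in an idealized 2D sheet of human ventricular myocardium.

## The problem

Surviving myocardium bordering a healed infarct scar is electrophysiologically
and structurally remodeled: its action-potential duration (APD) may be shorter
or longer than remote tissue, conduction is slowed (interstitial fibrosis
reduces transverse coupling; in healed infarcts conduction is often slow and
near-isotropic), and myofibers can be disarrayed. Spatial repolarization
gradients above roughly 3.2 ms/mm are an experimental substrate for
unidirectional block and re-entry, so *how the BZ is represented* in a
computer model directly changes its predicted arrhythmogenicity.

`bzsim` quantifies this with a fully controlled idealized model: a
30 x 30 mm triangulated sheet with an insulating 10 mm scar core (a real
hole in the mesh) and a 2 mm BZ annulus, in which three cellular APD
variants, three bulk-conductivity sets and two fiber-orientation modes are
combined into 12 BZ representations. For each it computes activation-time,
repolarization-time and repolarization-gradient maps.

## Model core

Transmembrane potential follows the monodomain equation

    beta * Cm * dV/dt = div(sigma grad V) - beta * (I_ion - I_stim)

with beta = 0.14 um^-1, Cm = 1 uF/cm^2, elementwise anisotropic bulk
conductivity sigma = R(theta) diag(sigma_l, sigma_t) R(theta)^T, and I_ion
from the 2006 ten Tusscher-Panfilov human ventricular model (epicardial
set). BZ APD variants scale the slow delayed-rectifier conductance g_Ks
(x0.5 longer APD, x2.0 shorter APD, ~+-40 ms at a 500 ms cycle length).
Discretization: P1 triangles with no-flux boundaries, lumped mass, operator
splitting (Rush-Larsen ionic update + implicit diffusion). Conduction
velocity (CV) is calibrated to targets by the fixed point
sigma <- sigma * (target/measured)^2. Details and numerical choices:
[docs/methods.md](docs/methods.md).

## Worked example

```python
from bzsim import (make_variant, pace_to_steady_state, measure_apd,
                   measure_cv, calibrate_conductivity)

apd, state = {}, {}
for variant in ("control", "longer_apd", "shorter_apd"):
    s, trace = pace_to_steady_state(make_variant(variant), 500.0, 100,
                                    record_last=1)
    state[variant], apd[variant] = s, measure_apd(trace)
    print(f"{variant:12s} APD90 = {apd[variant]:6.1f} ms")

cv_l = measure_cv(0.1890, 0.0690, "longitudinal", cell_state=state["control"])
cv_t = measure_cv(0.1890, 0.0690, "transverse", cell_state=state["control"])
print(f"CV along fibers  = {cv_l.velocity:.3f} m/s")
print(f"CV across fibers = {cv_t.velocity:.3f} m/s")

sigma, log = calibrate_conductivity(0.4, 0.0690, "longitudinal",
                                    cell_state=state["control"])
print(f"isotropic sigma for 0.4 m/s = {sigma:.4f} S/m ({len(log)} iterations)")
```

prints

```
control      APD90 =  284.5 ms
longer_apd   APD90 =  322.7 ms
shorter_apd  APD90 =  242.9 ms
CV along fibers  = 0.675 m/s
CV across fibers = 0.401 m/s
isotropic sigma for 0.4 m/s = 0.0690 S/m (1 iterations)
```

The halved/doubled g_Ks variants prolong/shorten the steady-state APD by
+38 / -42 ms; the normal anisotropic conductivities conduct at about
0.68 / 0.40 m/s along/across fibers on the 0.1 mm strip; calibrating an
isotropic tensor to 0.4 m/s lands on ~0.069 S/m.

The full sweep (maps and a gradient summary CSV for all 12 BZ
representations) runs from the shell:

```bash
bzsim study --preset desk --out study_out     # ~1 h at 0.15 mm, desk scale
bzsim run --apd shorter --cond decreased_transverse --fibers horizontal \
      --preset desk --out run_out             # one configuration, ~4 min
```

In the shorter-APD + decreased-transverse + horizontal-fiber representation
the repolarization gradient at the BZ edge peaks near 23 ms/mm at desk
resolution — far beyond the ~3.2 ms/mm block threshold — while normal-APD
representations stay comparatively smooth.

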