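# memp2rage

Simultaneous quantitative mapping of T1, T2\* and magnetic susceptibility
(χ) from a single multi-echo MP2RAGE acquisition — the signal model, the
estimators, the precision simulations and the test–retest statistics,
exercised end-to-end on a synthetic digital brain phantom so no scanner
data is required.

## The problem

MP2RAGE acquires two gradient-echo (GRE) image volumes at inversion times
T_I,1 and T_I,2 within each repetition and combines their complex signals
into the bias-cancelling uniform image

    ρ = Re[S₁* S₂] / (|S₁|² + |S₂|²),   ρ ∈ [-½, ½],

which depends on T1 (through the inversion recovery) but not on the
scanner gain, proton density or T2\* — so T1 follows from a lookup table
ρ(T1), with built-in insensitivity to B1⁺ inhomogeneity at 7 T.  Reading
several gradient echoes per k-space line turns the same scan into a T2\*
measurement (log-linear fit of the echo-magnitude decay) and, from the
phase of the longest echo, a quantitative susceptibility map via
Laplacian unwrapping, SHARP background removal, and thresholded dipole
inversion with D(k) = 1/3 − k_z²/|k|².

The package is aimed at quantitative-MRI researchers who want to
simulate, optimize or post-process such acquisitions: it provides the
closed-form two-block signal equations (validated against a brute-force
Bloch simulation), protocol feasibility arithmetic, the ρ→T1 lookup with
monotonic-branch detection, voxelwise T2\* fitting, the full QSM chain,
Monte-Carlo precision analysis of both estimators, a 3-D digital brain
phantom with published 7 T tissue values as ground truth, and the
voxel-by-voxel agreement statistics (μ_D, σ_D, μ_|D|, σ_|D|, r²) used
for test–retest comparisons.

## Worked example

Simulate the bundled 0.6 mm multi-echo protocol on the digital phantom at
image SNR ≈ 50 and recover all three parameters:

```python
import numpy as np
from memp2rage import (bundled_protocol, make_phantom, PhantomSpec,
                       simulate_acquisition, build_lookup, invert_rho,
                       rho_combine, echo_times, compute_chi)
from memp2rage.t2star_mapping import fit_loglinear_stack
from memp2rage.qsm import KGrid
from dataclasses import replace

p = bundled_protocol("me_mp2rage")          # TE = 2.35, 6.49, 10.63, 14.77 ms
truth = make_phantom(PhantomSpec())          # 64³ nested-ellipsoid brain
clean = simulate_acquisition(truth, p, 0.0, seed=1)
noise = np.abs(clean.inv2[0]).max() / 50     # image SNR ~ 50
acq = simulate_acquisition(truth, p, noise, seed=1)

lut = build_lookup(p)                        # rho(T1), 1 ms steps
t1, _ = invert_rho(np.asarray(rho_combine(acq.inv1[0], acq.inv2[0])), lut)

te = np.asarray(echo_times(p))
_, t2s, ok = fit_loglinear_stack(te, np.abs(acq.inv2))

fc = replace(acq.field_constants, te_qsm=float(te[-1]))
chi, er = compute_chi(np.angle(acq.inv2[-1]), truth.mask, fc,
                      KGrid(truth.labels.shape, truth.spec.voxel_size))

wm = truth.labels == 1
print(f"WM T1   : {1e3 * t1[wm].mean():.0f} ms   (truth 1219)")
print(f"WM T2*  : {1e3 * t2s[wm & ok].mean():.2f} ms  (truth 25.85)")
print(f"caudate - WM chi: "
      f"{chi[(truth.labels == 5) & er].mean() - chi[wm & er].mean():.1f} ppb")
```

prints

```
WM T1   : 1220 ms   (truth 1219)
WM T2*  : 26.02 ms  (truth 25.85)
caudate - WM chi: 13.3 ppb
```

White-matter T1 and T2\* come back at their ground-truth values (single
voxels scatter with the noise; class means are unbiased).  The recovered
caudate-vs-WM susceptibility contrast has the correct sign and ordering
but is ~0.7 of the true 19.3 ppb — the systematic attenuation of
truncated dipole inversion, discussed in `docs/methods.md`.

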