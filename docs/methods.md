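# Methods

## Signal model

The package models a magnetization-prepared two-block gradient-echo
acquisition (MP2RAGE) and its multi-echo extension (ME-MP2RAGE).  One
sequence period of duration `T_R,seq` consists of an adiabatic inversion
(efficiency `eta`, perfect inversion `eta = 1` by default since the pulse
efficiency is rarely reported), free relaxation over `T_A`, a first GRE
block of `n` spoiled excitations with flip angle `alpha_1` spaced by
`T_R,GRE`, relaxation over `T_B`, a second block with `alpha_2`, and
relaxation over `T_C`.  Every step acts on the longitudinal magnetization
as an affine map `mz -> a mz + b`; the steady state is the fixed point
`b/(1-a)` of the composed period map, reported immediately before the
inversion pulse.  Block signals at echo time `TE_i` are

    S_j(TE_i) = xi * sin(alpha_j) * Mz(center_j) * exp(-TE_i / T2*),

with `Mz(center_j)` obtained in closed form (geometric series of the
intra-block recursion) at the excitation of the k-space-center line.  The
closed form is verified against a brute-force time-stepped Bloch
simulation (relaxation and rotation per line, iterated to convergence) to
1e-14 relative; the test suite asserts 1e-6.

Signals are real-valued mono-exponential in `T2*`; water/fat phase
modulation, magnetization transfer and multi-compartment relaxation are
outside the model.  The two inversion contrasts combine into the uniform
image `rho = Re[S1* S2]/(|S1|^2+|S2|^2)`, which cancels the scanner gain,
proton density and `T2*` and is bounded in [-1/2, 1/2].

### k-space center position

The center of each block is reached after `round(f * n)` lines, where the
center fraction `f` defaults to 1/2 (full linear encoding).  The bundled
0.6 mm multi-echo protocol only fits its stated inversion times with
`f = 1/3`, the 6/8 partial-Fourier position, so the bundled file sets
that value explicitly.  Nominal flip angles are scaled by the B1+
efficiency factor `flip_accuracy` (`effective = flip_accuracy * nominal`)
before any signal computation; rounding to integer degrees is never
applied internally.

## T1 mapping

`rho(T1)` is tabulated at 1 ms steps over [0.1, 5] s by default — finer
than any effect the estimators resolve — and restricted to the largest
strictly monotonic branch containing T1 = 1.6 s (the WM/GM midpoint the
protocols are designed around).  Estimation inverts the branch by linear
interpolation.  `rho` values outside the branch are clamped to the
nearest endpoint and flagged rather than dropped, mirroring the
systematic CSF underestimation of protocols whose invertible range ends
near 3 s.  With the measured flip-angle efficiency 0.8 applied, the
bundled single-echo protocol's branch ends at 2.975 s (3.0 s when rounded
to 0.5 s); the multi-echo protocol remains invertible beyond 3.5 s.

B1+ sensitivity is explored by scaling both flip angles by `1 + offset`
(offsets of +-20% and +-40% reproduce the published curve families).  The
package quantifies, rather than corrects, this sensitivity: protocols are
chosen for insensitivity, and a lower steady-state magnetization (longer
`T_R,seq`) demonstrably shrinks the T1 error a B1+ offset induces.

## T2* mapping

Unweighted ordinary least squares of `ln S` on TE (slope `-1/T2*`),
solved by numpy's SVD-based least squares.  A magnitude-weighted variant
(first-order noise propagation of the log transform) exists behind a flag
but is off by default, matching the plain reading of a "log-linear least
squares" fit.  Voxels with any non-positive magnitude, fewer than two
echoes, or a non-negative slope are masked (T2* reported as +inf), never
raised as errors.  Magnitude noise is treated as Gaussian; the Rician
floor at low SNR biases T2* downward and is documented, not corrected.

## Susceptibility pipeline

1. **Laplacian unwrapping** — the Laplacian of the true phase is
   estimated from wrapped data via `cos p * lap(sin p) - sin p * lap(cos p)`
   and inverted spectrally (division by `-|k|^2`, zero frequency set to
   zero).  The result equals the true phase up to an additive harmonic
   component; net phase ramps across the volume are therefore not
   recoverable (irrelevant for the dipole fields simulated here).
2. **SHARP background removal** — spherical-mean-value filtering with a
   voxelized sphere kernel (radius 4 mm default), spectral deconvolution
   with frequencies where the filter magnitude falls below 0.05 zeroed,
   on the mask eroded by the kernel radius.  Fields of sources outside
   the mask are harmonic inside it and are annihilated; the deconvolution
   is exact only for sources whose convolved footprint survives the
   erosion, so structures close to the mask edge lose signal.
3. **ppb conversion** — division by `1e-9 * gamma * TE * B0`
   (`gamma = 2.675e8 rad/s/T`, `B0 = 7 T`, `TE = 14.77 ms` defaults; the
   longest echo is used for susceptibility because phase CNR grows with
   TE).
4. **Thresholded dipole inversion** — division by the unit dipole kernel
   `D(k) = 1/3 - k_z^2/|k|^2` with `|D|` floored at `kthresh = 0.2`
   (sign preserved), the truncation used by fast TKD-type methods.
   Because `D(0) = 0` the susceptibility offset is unidentifiable; maps
   are re-referenced to zero mean over the mask, so all values are
   relative to that arbitrary reference.

Voxel anisotropy is honored by physical frequency spacing in every
spectral grid.  SHARP radius/threshold and `kthresh` are not reported in
the source protocols; the defaults follow the cited methods' conventions
and are exposed in configuration.

**Known attenuation.** The kernel-magnitude floor attenuates the ~37% of
k-space lying near the magic-angle cone by a bounded factor.  On the
64-voxel-cube smooth-blob phantom the full chain recovers susceptibility
with regression slope ~0.79 and r^2 ~0.92 at zero noise; on the
nested-ellipsoid brain phantom the recovered caudate-minus-WM contrast is
~0.68 of truth (13.2 of 19.3 ppb) at the default `kthresh` — sign and
ordering of tissue contrasts are reliable, absolute contrasts are
systematically underestimated, as is characteristic of truncated dipole
inversion.

## Monte-Carlo precision simulations

For each of 100 (configurable) true relaxation times, noise-free signals
are synthesized from the sequence model, Gaussian noise is added over N
repetitions, and the estimator's spread `sigma_T` is summarized by its
mean and SD over the range.  SNR is defined as the maximum noise-free
signal over the scanned range divided by the noise SD, applied
identically to all images so SNR = 25/50/100 are comparable across
protocols.  N defaults to 2000 — the spread estimate then carries ~1.6%
relative Monte-Carlo error, ample for the 15% oracle tolerance — and can
be raised to 20000.  Noise draws are generated in an order independent of
the SNR value, so runs differing only in SNR are paired comparisons.

Two T1 estimators are provided: a two-parameter (scale + T1) fit of the
two signal magnitudes (a grid search over T1 with the scale profiled out
analytically, refined parabolically), and the uniform-image lookup
applied to noisy signed signals.  The magnitude fit degrades near the
zero crossing of the first-block signal (T1 ~ T_I,1 / ln 2) where
magnitude data carry almost no information — the reason the lookup-based
reconstruction is preferred in practice.  The log-linear T2* fit is
validated against the closed-form OLS variance propagation; repetitions
whose noisy magnitudes are not all positive cannot be log-fit and are
dropped and counted.

## Digital brain phantom

A nested-ellipsoid geometry (64^3 voxels, 0.6 mm isotropic by default): a
cortical gray-matter shell around a white-matter interior, a CSF core,
and bilateral putamen, caudate and thalamus nuclei.  Class values default
to the 7 T in-vivo ROI group means (cortical GM takes the frontal-lobe
column; susceptibility is referenced to that table's arbitrary zero).
CSF T1 (4.3 s) and T2* (50 ms) are not in that table; they are synthetic
literature-typical 7 T values chosen to exercise lookup clamping.  M0 is
a plausible relative proton density per class.  Optional per-class jitter
uses the published per-class SDs.

The forward simulator composes the block signal model (with an optional
smooth B1+ multiplier field on the flip angles) with the spectral dipole
field of the susceptibility map: phase at echo TE is the wrapped field
phase, complex Gaussian noise is added per echo volume, and all
randomness flows from one seed (bitwise reproducible).  Noise is added to
the complex data here — this module feeds the phase pipeline — whereas
the Monte-Carlo module adds magnitude noise; the two choices are
deliberate and separate.

What the phantom does *not* emulate: anatomical geometry, k-space
undersampling and partial-Fourier artifacts, coil-combination pole
artifacts, motion, physiological noise, background fields from air-tissue
interfaces (a smooth polynomial stand-in can be injected), or
multi-compartment relaxation.  Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not in-vivo accuracy.

## Agreement statistics

For test map x and reference y over N masked voxels, D = y - x:
`mu_D` (accuracy), `sigma_D` (precision), `mu_|D|` and `sigma_|D|`
(overall reproducibility), and the squared Pearson correlation r^2.  The
default `sigma_|D|` centers |D| on `mu_D`, reproducing the printed
definition in the source publication even though conventional practice
would center on `mu_|D|`; both are computed and reported (they disagree
exactly when D is symmetric about zero, e.g. x=(0,0), y=(1,-1)).

Mis-registration sweeps apply known rigid transforms (axial rotation
about the FOV center, then axial sub-voxel translation, trilinear or
nearest resampling; out-of-volume samples are invalidated) and tabulate
the statistics of map vs moved map.  Fine-textured maps (T2*-like) lose
r^2 much faster than smooth (T1-like) maps under half-voxel offsets.
Recovering unknown transforms (registration proper) is out of scope.
The noise sweep re-runs the full susceptibility chain on complex data
with added Gaussian noise and compares each map to the zero-noise
baseline; r^2 degrades monotonically with noise SD while `mu_D` stays
near zero (zero-mean noise propagates to near-zero map bias).

2-D correlation histograms default to 128 bins per axis over each map's
central 99% value range.

## Numerical conventions

- Spectral grids put the zero frequency at index 0; anisotropic voxel
  sizes enter through physical frequency spacing.
- `round(f * n)` uses round-half-up so the center-line index is
  deterministic across platforms.
- Monotonic-branch selection breaks ties (equally long branches both
  containing 1.6 s — impossible for strictly monotonic runs, guarded
  anyway) in favor of the first.
- Phase is stored wrapped to (-pi, pi]; complex volumes are written as
  magnitude + phase NIfTI pairs (scanner convention).
- Problem sizes in the test suite: 64^3 phantom grids, 20-point T1 grids
  for oracle equivalence, N = 2000 Monte-Carlo repetitions, 15 probed
  relaxation values per run; these keep the whole suite around ten
  seconds on one CPU while leaving Monte-Carlo errors well below the
  asserted tolerances.

## Known limitations

- The signal model is spoiled-GRE only; transverse coherences are not
  modeled.
- Gaussian (not Rician) magnitude noise biases low-SNR T2* estimates.
- Truncated dipole inversion underestimates susceptibility contrast by
  the cone factor (~0.7-0.8 at `kthresh = 0.2`); no streak-suppressing
  regularized inversion is provided.
- The total acquisition time printed in protocol tables cannot be
  reconstructed without the outer-loop step count (oversampling and
  partial-Fourier bookkeeping), so `total_time` takes it explicitly.
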