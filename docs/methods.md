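# Methods

## The membrane model

The package implements a four-current semiphysiological ventricular
action-potential model. The dimensionless transmembrane voltage
V = (Ṽ − Ṽ_rest)/ΔṼ (Ṽ_rest = −85 mV, ΔṼ = 100 mV, so V runs
roughly from 0 to ~1–1.5) obeys

    ∂V/∂t = ∇·(D∇V) − (J_fi + J_si + J_so + J_to) + J_stim ,

with four scaled currents (units ms⁻¹):

* J_fi = −g_fi · h · m∞(V) · (V_fi − V): fast inward, sodium-like,
  gated by the inactivation variable h; m∞ = (V−V_c)·Θ(V−V_c) is the
  instantaneous piecewise-linear activation.
* J_si = −g_si · d∞(V) · f · f′∞(V): slow inward, L-type-calcium-like,
  gated by the inactivation variable f; d∞ and f′∞ are sigmoids
  (tanh with slopes β₁, β₂ centered at V₁, V₂), and d∞ carries the
  threshold step Θ(V−V_c).
* J_to = g_to · r · s · (V − V_to): fast transient outward,
  I_to-like, with dynamic activation r and inactivation s.  This
  current produces the phase-1 notch of epicardial action potentials
  and is the model's distinguishing addition over three-current
  predecessors.
* J_so = g_so · k∞(V): time-independent slow outward
  (delayed-rectifier-like); k∞ rises linearly to 1 at V_c and
  saturates.

Each dynamic gate relaxes as ġ = (g∞(V) − g)/τ_g(V) with step-function
steady states and two-valued time constants: h, f switch at V_c, r at
V_r = 0.6, and s at the per-cell-type threshold V_s (see below).  Five
built-in parameter sets reproduce the published table: fits to human
epicardial, endocardial and midmyocardial myocyte recordings, and fits
to the ten Tusscher et al. human (TNNP) and Luo–Rudy dynamic guinea-pig
(LRd) ionic models.  V_r = 0.6 and V_to = 0 are fixed for all sets.

Design choices where the defining equations leave freedom:

* **Θ(0) = 1** (right-continuous Heaviside), centralized in one
  helper.  This keeps k∞ continuous at V_c; everywhere else the choice
  is measure-zero.
* **Role of V_s.** The printed gate equations switch the s gate at
  V_c, which would leave the tabulated per-cell-type V_s unused.  We
  interpret V_s as the s-gate switching threshold (s∞ = 1 − Θ(V−V_s),
  τ_s switching at V_s); the literal reading is available via
  `ModelParameters(s_gate_threshold="Vc")`.
* **Stimulus sign.** Stimulus amplitude is exposed as a depolarizing
  magnitude added to dV/dt, matching the physiological meaning of
  "threshold stimulation".
* **Initial condition** is the analytic resting fixed point
  (V=0, h=1, f=1, r=0, s=1), at which all four currents vanish
  identically.

## Numerics

Time integration is forward Euler at dt = 0.01 ms (the model's
published operating point); space is a uniform grid, dx = 0.02 cm in
1D/2D and 0.025 cm in 3D.  The diffusion operator is a conservative
flux-form finite difference: the divergence at a node is the signed sum
of face fluxes divided by dx, a face flux exists only between two
in-tissue nodes (zero-flux boundaries), and consequently ΣV over the
tissue is exactly conserved under pure diffusion.  For anisotropic
tissue each node carries a symmetric tensor
D = D_⊥ I + (D_∥ − D_⊥) f f^T built from the local fiber unit vector f
(defaults D_∥ = 10⁻³, D_⊥ = 6.75×10⁻⁵ cm²/ms, a ~3.85:1 velocity
ratio); face tensors are arithmetic means of the adjacent node tensors
and cross-derivative terms use face-averaged tangential gradients, so
conservation is preserved.  The explicit stability bound
dt < dx²/(2·ndim·D_max) is checked at construction (configurable
warn-or-abort, default abort).

Two performance choices, both invisible at the model's accuracy level:

* The tissue kernels evaluate the two tanh-based gate curves
  (d∞, f′∞) from a 4096-point lookup table over V ∈ [0, 2.6] with
  linear interpolation (absolute error < 10⁻⁵, far below the O(dx)
  front-discretization error).  The single-cell integrator and the
  reference API use exact tanh.
* Stimulus currents are piecewise constant over output-sampling
  windows (default 1 ms), which is exact for the integer-millisecond
  protocols used throughout.

Mesh sensitivity: with step-function gates the depolarization upstroke
spans ~1 ms, so the traveling front is only one or two nodes wide at
dx = 0.02 cm and the measured conduction velocity retains a
noticeable lattice deficit at the standard resolution (CV rises from
57.3 cm/s at dx = 0.02 toward ~68.7 cm/s as dx, dt → 0 for the
LRd-fit set at D = 10⁻³ cm²/ms; an independent adaptive-step
method-of-lines integration agrees with the fine-grid limit).
Convergence is monotone and first order.  All headline numbers in this
package are therefore quoted at the standard operating point
(dx = 0.02 cm, dt = 0.01 ms) rather than the continuum limit.

## Measurement protocols

* **Excitation threshold**: bisection (relative tolerance 10⁻³) on the
  amplitude of a 1-ms pulse from rest; success = V exceeds 0.8 within
  20 ms.  Protocols stimulate at 1.5× threshold by default.
* **APD / DI**: APD is time above V = 0.1 (≈ −75 mV, ~90%
  repolarization), DI the gap between a repolarization and the next
  activation; threshold crossings are linearly interpolated between
  samples.  Activation times for CV use the upstroke crossing of
  V = 0.5, where the wavefront is steepest and the choice is least
  sensitive.
* **Dynamic restitution**: pace at fixed BCL for 10 beats (the model
  has no ion-concentration memory, so the periodic state is reached
  within a few beats), record the final beat; BCLs that lose 1:1
  capture are reported as dropped, not interpolated.
* **CV restitution**: 8 cm cable, probes at 3 and 5 cm (≥ 1 cm from
  either end), CV from the final-beat activation-time difference.
* **Spiral initiation**: S1 plane wave from the left edge; S2 over the
  lower-left quadrant, auto-timed to the moment the domain-center node
  repolarizes below the APD threshold, which places the S2 edge inside
  the recovering wake and leaves a single free end that curls into a
  rotor.
* **Tip tracking**: per frame pair, ∂tV by forward difference; within
  each grid cell the V = V_iso and ∂tV = 0 contours are interpolated
  bilinearly and their intersection solved in closed form; points are
  linked over time by nearest neighbor within 0.5 cm (optionally
  seeded).  V_iso defaults to half the maximum voltage of the series;
  the published definition ("half the maximum depolarization") is
  ambiguous in dimensionless units, and the trajectories are only
  weakly sensitive to the choice.
* **Spiral statistics**: discard ≥ 500 ms after initiation, then mean
  inter-activation interval at a fixed probe (≥ 5 rotations), with the
  consistency identity T = APD + DI enforced within 1 ms.  Because the
  core meanders, the period is weakly probe-dependent (Doppler shift);
  `measure_spiral_period` ranks candidate probes by distance from the
  tip trajectory and uses the farthest one at least 2 cm away whose
  statistics satisfy the identity.  On the 6×6 cm domain used for the
  standard study the probe-to-probe spread of T is a few ms.

## Synthetic ventricles and pseudo-ECG

No anatomical reconstruction is bundled; the geometry module builds a
parametric stand-in: two nested truncated ellipsoidal shells — a thick
left-ventricular wall and a thinner right-ventricular crescent sharing
a septum — with closed blood cavities (verified by connected-component
count), circumferential fibers (ẑ × ρ̂ around the long axis), and the
published voxel size (0.025 cm) in a box far inside the published
152×138×130 bound.  Endocardial voxels are those adjacent to a cavity.
The His–Purkinje system is emulated exactly as in the source study, by
timed endocardial stimuli: the septal endocardium from base to
mid-level at t = 0 ms, mid-level to apex at t = 5 ms, and the
remaining (free-wall) endocardium at t = 10 ms, repeated at the pacing
BCL.  Real anatomies can be dropped in through the geometry container
(voxel mask + fiber field + region labels, `.npz`).

The pseudo-ECG uses the far-field heart-dipole approximation for a
homogeneous torso: J⃗(t) = Σᵢ r⃗ᵢ [∇·(D∇V)]ᵢ dx³ over tissue voxels,
with r⃗ᵢ measured from the tissue centroid (the choice is immaterial:
on a no-flux domain the source term sums to zero, making J⃗
origin-independent, which is tested).  The same conservative diffusion
operator as the solver supplies the source term.  Lead I is the
projection on the box x-axis (the monodomain model defines no torso
frame); amplitudes are arbitrary and waveforms are normalized to unit
peak |deflection| in the activation window.  Chest leads are out of
scope (they require a torso model).  With a single homogeneous
parameter set the repolarization deflection is discordant (opposite in
sign) to the main activation deflection, because repolarization
retraces the activation sequence — reproducing the inverted-T
observation for homogeneous ventricles; transmural heterogeneity would
be needed for a concordant T wave and is not modelled.

## Parameter fitting

`fitting` estimates free parameters by bounded trust-region least
squares (a Levenberg–Marquardt-type scheme, `scipy.optimize
.least_squares`).  The objective simulates the cell to its final
pre-beat at each template's BCL, aligns model and template at the
V = 0.5 upstroke crossing (the data provide no absolute clock), and
returns weighted pointwise voltage residuals, optionally concatenated
with scaled CV residuals from a short-cable run so AP shape and
conduction can be fitted simultaneously.  "Slightly larger weight on
the notch" is quantified as ×3 over the window from upstroke+5 ms to
upstroke+50 ms (both configurable).  Simulation failures return large
finite penalty residuals so the optimizer can retreat.  The landscape
has many local minima in the full parameter space; the default is a
single start from the user's guess, with optional seeded multi-start
jitter (deterministic per seed, best-of-starts returned, all starts in
the diagnostics).  Which parameters to free is the user's choice
(exposed as `FitProblem.free`); the default subset
(conductances + the time constants that shape a single steady-state
beat: τ_f−, τ_r+, τ_s−) is well identified by two-rate AP templates,
whereas g_fi (which shapes only the sub-millisecond upstroke) and
recovery constants such as τ_h+ need conduction-velocity or
fast-pacing data to pin down — which is why the original fits included
CV targets simultaneously.

## Problem sizes of the standard studies

The shipped studies (tests and the reproduction script) use: 8 cm
cables at dx = 0.02 cm; a 6×6 cm sheet (301² nodes) integrated ~2.5 s
of model time for the spiral study (S1–S2 initiation plus a 2 s
measurement window, ~14 rotations); and a 72×68×64-voxel synthetic
ventricle (~42k tissue voxels) paced for four beats at BCL = 400 ms
for the ECG study.  The sheet is smaller than the 10×10 cm domain of
the original spiral figures and the measurement window shorter than
4 s; a one-off 10×10 cm control run reproduces the same period within
the probe-to-probe Doppler spread.  All protocols are deterministic;
the only randomness anywhere is the optional fitting multi-start
jitter, which is seeded.

## What the synthetic studies do and do not show

All validation here is against the model's own published operating
point and internal consistency (oracle integrators, conservation,
scaling laws, self-fit recovery): there is no bundled experimental
data.  Passing tests demonstrate that the equations are implemented
faithfully and measured as described — not that the model reproduces
any particular heart.  Known limitations inherited from the model
itself: no intracellular ion-concentration dynamics (hence no slow
memory, no S1-S2 vs dynamic restitution distinction), no Markov
channel gating, no electrophysiological meaning for individual lumped
currents, and a homogeneous-torso single-lead pseudo-ECG only.
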