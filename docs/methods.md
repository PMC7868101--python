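# Methods

`sosperf` is a desk-scale simulator and reconstruction/analysis toolkit for
free-breathing 3D stack-of-stars (SOS) first-pass myocardial perfusion (FPP)
imaging.  This note records the models implemented, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Acquisition model

k-space is sampled with radial spokes in-plane and a Cartesian
phase-encode ladder along the slab axis (kz "partitions").  One image
frame is acquired per cardiac cycle (a "shot"); within a shot every spoke
angle is acquired at every partition.

* **Angles.** Spokes advance by the golden angle
  `pi*(sqrt(5)-1)/2 ≈ 1.941611 rad ≈ 111.246°`, continued across the whole
  series by default, so any contiguous subset of spokes covers the
  half-circle near-uniformly (the three-distance theorem bounds the gap
  structure; this is asserted by enumeration in the tests).  A per-frame
  restarted schedule is available.
* **Partitions.** The default stack has 16 partitions of 5 mm; the slab
  edges are excited imperfectly in any 3D acquisition, so the analysis
  discards 2 slices from each end, displaying 12.  kz is ordered
  centrically (centre of k-space first) so that the contrast-defining data
  coincide with the end-systolic pause to which the shot is timed.
* **Shot duration accounting.** `shot_duration = TR x spokes/frame x
  partitions`.  The packaged defaults — TR 2.35 ms, 5 spokes/frame, 16
  partitions — are this package's own choice of a plausible line budget
  whose product is the 188 ms shot the sequence is designed around; they
  are not a claim about any particular scanner protocol.
* **Coordinates.** In-plane k is normalised to cycles per pixel with
  `|k| <= 0.5`; image grids use the centre-origin DFT convention (DC at
  index N/2).  Readout oversampling is 2 by default.

## Phantom

The left ventricle is an analytic ellipsoidal shell (per slice: an annulus
whose endo/epi radii follow elliptical long-axis profiles), rasterised
fresh every frame so that rigid motion introduces no interpolation blur.

* **Arterial input.** A gamma-variate bolus
  `c(t) = A ((t-t0)/(alpha*beta))^alpha exp(alpha - (t-t0)/beta)` for
  `t > t0`, peak value `A` at `t0 + alpha*beta`.  Defaults `A = 5 mM`,
  `t0 = 3 s`, `alpha = 2.5`, `beta = 1.5 s` give a first-pass bolus peaking
  ~7 s after injection, a plausible LV bloodpool profile for a compact
  power-injected bolus.
* **Tissue kinetics.** One-compartment uptake
  `C(t) = Ktrans * int aif(tau) exp(-kep (t-tau)) dtau` by trapezoidal
  convolution.  Defaults `Ktrans = 0.025 /s`, `kep = 0.10 /s` correspond to
  stress-level myocardial flow with an extraction-fraction-scaled transfer
  constant of ~1.5 /min and ve ~ 0.25.  Defects scale `Ktrans` by
  `(1 - flow_reduction)` over a wedge defined by an angular span, a
  partition span and a transmural fraction measured from the endocardium.
* **Signal.** Saturation recovery `S = M0 (1 - exp(-TS (R1_0 + r1 C)))`
  with `TS = 100 ms`, `r1 = 4.5 /(mM s)`, `R1_0 = 0.83 /s` (myocardium) and
  `0.62 /s` (blood) — 3 T values.  Kinetic defaults were chosen once to
  satisfy the qualitative orderings of a first pass (bloodpool peaks
  before myocardium; defect depth increases with flow reduction); they are
  not fits to patient data and are not presented as such.
* **Motion.** Respiration is a rigid sinusoidal translation (default
  amplitude (3, 2, 0) mm in (z, y, x), period 4.2 s), one position per
  cardiac cycle; intra-shot motion is out of scope.  Mis-triggered frames
  (Bernoulli with configurable probability; offsets uniform in ±RR/2)
  receive an extra in-plane displacement standing in for the wrong cardiac
  phase.
* **Dark artefacts are not injected.**  Transient hypointensities are left
  to emerge from angular undersampling of the sharp bloodpool/myocardium
  edge, which is how their clinical counterparts behave.

All randomness flows from one integer seed through named
`numpy.random.Generator` streams.

## Encoding

The forward operator per frame is: coil-sensitivity multiplication, an
FFT along kz, and an in-plane type-2 nonuniform Fourier transform at the
frame's spokes; receiver noise is circular complex Gaussian in k-space.
Two interchangeable backends implement the in-plane transform:

* an exact direct-summation DFT (the oracle; used on grids ≤ 32²), and
* a Kaiser–Bessel gridding NUFFT: 2x oversampled FFT grid, kernel width 7
  with the Beatty beta, analytic sinh-form deapodisation.  Width 7 was
  chosen so backend agreement (~6e-7 relative) comfortably meets the
  1e-5 operator-equivalence contract; width 4 cannot.

The adjoint is the exact conjugate transpose within each backend (the
dot-product test holds to ~1e-15).  Coil maps are smooth synthetic
Gaussian bumps on a ring around the FOV and are treated as known;
sensitivity estimation is out of scope.

## Reconstruction

* **Gridding** — density-compensated adjoint with ramp weights
  (`w ∝ |k|`); the DC sample receives the continuum-limit ramp weight
  `Δk/8` per spoke; weights are normalised so their total equals the
  sampled k-space disc area, which makes a fully sampled unit object
  reconstruct near unit magnitude.
* **STCR** — minimises

      J(m) = ||E m - d||² + α_t Σ √(|Δ_t m|² + ε²)
                          + α_s Σ √(|Δ_x m|² + |Δ_y m|² + ε²)

  with forward differences, temporal across frames (no wraparound),
  isotropic in-plane spatial TV, and no kz smoothing.  The optimiser is
  plain gradient descent with Armijo backtracking (c = 1e-4, shrink 0.5),
  the simplest scheme consistent with a smoothed-TV cost; the accepted
  cost trace is nonincreasing by construction.

Numerical choices that matter:

* **Weight scaling.** The solver normalises the image to the scale of the
  density-compensated adjoint and multiplies the configured weights by a
  power-iteration estimate of `λ_max(E^H E)`, so `alpha_t`/`alpha_s` are
  dimensionless and the same numbers act identically across grid sizes,
  coil counts and data scales.  The default `alpha_t = 0.01`,
  `alpha_s = 0.2 * alpha_t` sits at the corner of converged L-curves on
  the default phantom and is *not* re-tuned per case.
* **Initial step.** `1/(2 λ_max)`, the inverse Lipschitz constant of the
  fidelity term — robust from any start point; the step doubles after each
  accepted iteration and is halved by backtracking.
* **TV smoothing ε.** Default `1e-8 x median |d|`, i.e. effectively exact
  TV.  For L-curve sweeps the default configuration raises ε to 1e-3 on
  the normalised image scale: corner detection compares neighbouring
  minimisers whose differences are otherwise smaller than the convergence
  error of a first-order method on a near-nonsmooth cost.
* **L-curve.** Solves on an ascending alpha grid (all cold-started from
  the gridding adjoint — warm-start continuation can stall gradient
  descent where the near-exact TV gradient is flat), then picks the
  maximum three-point Menger curvature of the (log residual, log penalty)
  polyline.  Degenerate grids return the single point (or the smallest
  alpha for two points).

## Analysis

Reconstructed series are read the way dynamic perfusion series are read
clinically:

* slices are banded basal/mid/apical by thirds of the LV long axis and
  divided into the 16 AHA segments (6+6+4; anatomical angle 0° = anterior,
  clockwise through the septum); each segment is split at mid-wall into
  endo/epi halves;
* a segment is hypointense at frame t when its mean magnitude drops below
  `remote(t) x (1 - threshold_frac)`; the remote reference is the mean of
  segments that never dip (median of all segments if every segment dips —
  a logged global-artifact fallback).  Detection starts at bolus arrival
  (bloodpool above 20% of its peak).  Segment-frames with no voxels
  (apical band drifting out of the retained slices under respiratory
  z-shift) are excluded rather than read as zero signal;
* runs of hypointense frames lasting at least `persist_min` (default 5)
  that extend beyond ± `artifact_window` (default 3) frames around the
  bloodpool peak are persistent defects; every other run — in particular
  the 2–3-frame dips that ride the contrast peak, the dark-rim-artefact
  signature — is a transient artefact.  `threshold_frac` defaults to 0.15;
* severity is the composite `depth x transmurality x min(1,
  persistence/pass_length)` graded at 0.5 / 0.2 / 0.05 for
  severe/moderate/mild.  These thresholds are declared conventions for an
  automatic reading, exposed in configuration — human readers grade by
  impression, and no agreement with any particular reader panel is
  claimed.  Transmurality is estimated from the ratio of endo-half to
  epi-half deficits (0.5 = subendocardial, 1.0 = transmural).

## Reference studies and problem sizes

The evaluation module re-runs the whole chain at sizes chosen to show the
effects in minutes on one CPU: operator checks on 16×16×4 grids; gradient
checks on 8×8×2×3; convergence on fully sampled 32×32×4; regularisation
behaviour on a static ringed object at 32×32×2×8 with 8x angular
undersampling; defect recovery on a 64×64×8, 24-frame stress phantom with
a severe transmural (flow reduction 0.8) and a mild subendocardial (0.3)
wedge at 8x undersampling with receiver noise, against a defect-free
control.

## What the synthetic experiments do and do not show

The phantom reproduces the *structure* of a first-pass exam — kinetics,
contrast, undersampling, breathing, triggering — not its full physics.
There is no B0/off-resonance model, no intra-shot motion, no realistic
torso or coil load, no dark-rim physics beyond what undersampling
produces, and the anatomy is a smooth shell.  Passing tests therefore
demonstrate that the operators, solver and classifier are correct and
behave as designed under controlled conditions; they do not certify
diagnostic performance on patient data.  Consistent with the motivating
clinical experience, the mild subendocardial defect in the recovery study
sits near the detection threshold and may be missed — the study asserts
the severe defect's recovery and the absence of false positives, not
sensitivity to mild disease.

## Known limitations

* Plain gradient descent converges slowly on the near-exact TV cost;
  hundreds of iterations are needed for tightly converged solutions
  (the L-curve study budget).  A proximal or quasi-Newton scheme would be
  faster but is deliberately out of scope.
* The analysis consumes the phantom's ground-truth geometry (simulation
  mode); LV segmentation of reconstructed images is not implemented.
* Respiratory motion is rigid translation only; rotation and deformation
  are not modelled.
* The HDF5 raw layout is self-defined (ISMRMRD-inspired), not a vendor or
  community standard.
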