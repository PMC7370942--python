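# Methods

## Model and assumptions

capreg estimates per-channel scalp positions from a colored point cloud
of a cap-mounted head. Its geometric model makes three assumptions:

1. **The cap is rigid up to rotation and two scales.** A probe-holding
   fNIRS cap does not stretch like an EEG net; relative to the head it
   can rotate globally and scale along the anterior–posterior and
   left–right axes. All placement variation is therefore captured by the
   positions of the nine fiducials (three head-anchored: Nz, AL, AR; six
   cap-mounted: Cz, Pz, Iz, FRONT, LEFT, RIGHT). Cz is a cap marker
   placed at the correct scalp position, so it also serves as the fourth
   head anchor for the MNI fit.
2. **Probes are affine functions of the fiducials.** Pre-registration
   writes each model-cap probe as p_j = Σᵢ w_ij·f_i with Σᵢ w_ij = 1.
   The system (three coordinates plus the sum constraint; nine unknowns)
   is underdetermined; the minimum-norm solution is used because it is
   unique and inherits the sum-to-one property, which makes the
   interpolation exactly equivariant under any affine map of the
   fiducials. That equivariance is what lets the same weight rows be
   applied after the head-to-MNI transform, and what lets a subset of
   ≥ 5 recovered fiducials (weights re-solved on the model's matching
   subset) still determine every channel.
3. **Head-to-MNI is rotation + translation + AP/LR scaling.** Fit by
   Levenberg–Marquardt on the four head anchors, initialised from the
   closed-form similarity (Umeyama) fit; scales are optimised in log
   space so they stay positive. The vertical scale is fixed at 1 by
   default (`free_vertical` releases it) because only the AP and LR axes
   are physically free.

## Fiducial labeling

Cluster centroids arrive unnamed. The labeling search enumerates
hypotheses (unordered centroid triple × ordered model-label triple);
each hypothesis fits a closed-form three-point similarity transform
(rotation, uniform scale, translation — the minimal family consistent
with the rigid-cap assumption), maps the remaining model fiducials
through it, and is scored by the cost of the optimal one-to-one
assignment (Hungarian) of remaining model points to remaining centroids.
Independent nearest-neighbour matching would allow double-matching; the
assignment forbids it. With ≤ 9 centroids the enumeration is exhaustive;
above that, centroid triples are sampled with the caller's seed
(`max_iterations`, default 2000). A vectorised lower bound (sum of
per-point nearest distances, which can only undershoot an assignment
cost) orders the hypotheses so exact assignment costs are evaluated only
until the bound passes the best cost found — the result is identical to
full enumeration. Ties break toward the lexicographically smallest label
triple, making the search deterministic. Collinear triples (relative
cross-product tolerance 1e-6) are skipped; if every hypothesis is
degenerate the search fails loudly.

Missing stickers: with 5–8 centroids the unmatched labels are reported
absent and downstream stages use the layout's redundancy (five cap+head
points suffice; six cap stickers are carried).

## Frame masking

- **White balance**: gray-world (each channel scaled to the global gray
  mean, clipped to [0, 255]). Idempotent up to rounding unless gains
  push pixels into saturation.
- **Sticker rule**: ≥ 5 connected pixels (8-connectivity, robust to
  diagonal chains) within ±`hue_tol` of the sticker hue. The tolerance
  is a fraction of the normalised hue circle, default 0.15 (±54°);
  comparisons wrap around the circle. The circle around a cluster is the
  exact minimum enclosing circle (Welzl's algorithm) of the component's
  pixel centres, inflated 20 %; the margin is applied to the continuous
  radius before any rasterisation.
- **Cap segmentation** is a pluggable contract (any Frame → boolean-mask
  callable, e.g. a trained CNN); the built-in fallback thresholds the
  two cap-pattern hue bands with a minimum saturation of 0.25 so that
  gray/black pixels, whose hue is meaningless, cannot match.
- **Rejection**: a frame is dropped iff strictly more than
  `reject_threshold` (default 0.98) of it is blackened; a frame at
  exactly the threshold is kept.

## Session statistics

Distances and shift angles are Euclidean/geometric, hence invariant
under any common rigid transform of the measurements. Summaries are
mean ± SD across subjects of within-subject channel means. Angles
between zero-length shifts are undefined: they are reported as missing
and excluded from the KS input rather than silently dropped. The KS test
is one-sample against uniform on [0°, 180°] with the asymptotic p-value.
The shift-size association is pooled OLS of method B's sizes on method
A's with the slope's F test on (1, n−2) df; a subject-level
mixed-effects model would be the fuller analysis, and every report notes
the simplification.

## Synthetic scenes

The generator replaces real recordings, so its defaults define the study
conditions:

- **Head**: an ellipsoid, default semi-axes (80, 95, 90) mm (LR, AP,
  vertical), 2000 surface points. Fiducial directions come from a
  shipped table of canonical 10-20-like unit directions projected onto
  the ellipsoid; twelve probes sit between fiducial pairs. Everything is
  analytic, so ground truth is exact.
- **Cap placement**: `simulate_subject` applies p′ = S·R·p (S =
  diag(scale_lr, scale_ap, 1), R from extrinsic x-y-z Euler angles) to
  the cap markers and probes about the head centre; head fiducials stay
  put. `sample_cap_misplacement` draws the study condition: twist about
  the vertical axis up to ±30°, pitch/roll up to ±10°, AP/LR scales
  uniform in [0.9, 1.1]. The tilt bound reflects how a soft cap can
  physically sit — its edge hugs the head, so large pitch/roll would
  slide cap-edge stickers onto the head stickers (at ~30° tilt the
  ear-region stickers pass within the 10 mm linkage radius and merge,
  a configuration no usable recording would produce).
- **Sticker clusters**: each fiducial is emitted as 200 vertices
  (default) with isotropic Gaussian noise, default sd 0.5 mm — the
  scale of SfM reconstruction noise the error budget targets. Sticker
  color defaults to saturated green; physical sticker diameter (used by
  the renderer) defaults to 10 mm.
- **Cap pattern**: 2-D lattice gradient noise, 4 octaves, min-max
  normalised and thresholded into the two cap colors. Any feature-rich
  two-color pattern serves the purpose; this one is deterministic per
  seed.
- **Frames**: pinhole projection, head vertices splatted as cap-colored
  disks over a light background, camera-facing fiducials (radial
  visibility test on the convex head) drawn last as sticker-colored
  disks of ≥ 3 px radius, with per-frame ground-truth pixel centres
  returned.

What the synthetic study does **not** emulate: SfM artifacts with
structure (drift, patchy coverage, outlier fragments), cap-cloth
deformation, hair and skin tones, specular lighting, occlusion by
hands or parents, and real anatomical head shape. Passing tests
therefore demonstrate the correctness and noise behaviour of the
geometry/labeling/registration machinery, not field performance on real
videos.

## Ground truth for the end-to-end error

The end-to-end study reports the error between the pipeline run on noisy
clusters and the same computation run on the exact fiducial positions.
This isolates what the software adds (clustering, labeling, fitting,
interpolation) from the barycentric model's own approximation on a
deforming head, and gives an error that provably vanishes as the vertex
noise goes to zero. Measured at noise sd 0.5 mm over 20 placements the
RMS channel error is ≈ 0.05 mm, two orders below the 2 mm scale the
method needs to beat to be useful.

## Numerical choices and problem sizes

- Weight-solve residual must stay ≤ 1e-6 mm or the model is declared
  degenerate; weight rows sum to 1 within 1e-9 by construction.
- The head-transform fit runs to machine tolerance (xtol/ftol/gtol
  1e-15); noiseless parameter recovery is ~1e-14.
- Labeling tie epsilon 1e-12 mm; point-cloud linkage radius default
  10 mm and minimum cluster size 5 (the cloud-space analogues of the
  frame-space 5-pixel rule; both configurable, chosen for 10 mm stickers
  and millimetre-scale noise).
- PLY vertices are stored at float32 precision (~6e-6 mm at 95 mm), so
  file round trips bound any exactness statement through files; the
  in-memory pipeline reproduces model probes to better than 1e-9 mm.
- Default study sizes — 2000 head vertices, 200 points per sticker,
  20 placements for the error study, 100 configurations for the
  labeling study — keep a full validation run around a minute on one
  CPU while the Monte-Carlo standard errors stay well below the margins
  being tested.

## Known limitations

- The similarity-based labeling can in principle confuse cap-edge and
  head stickers under extreme (physically implausible) tilts that bring
  them closer than their model-space neighbours; within the study
  conditions this never occurs (100/100 configurations correct).
- CNN cap segmentation and face-landmark detection are external; the
  shipped fallbacks are color-threshold and landmark-input stand-ins.
- Structure-from-motion reconstruction is out of scope: capreg consumes
  its output cloud (documented handoff: PLY with per-vertex uchar RGB,
  mm units).
- No anatomical atlas: outputs are MNI scalp coordinates; lobe-level
  labeling of channels is not attempted.
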