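# capreg

Automatic video-based spatial co-registration of scalp-mounted fNIRS/EEG
probes.

Functional near-infrared spectroscopy measures brain activity through
optodes held on the scalp by a soft cap. Interpreting a recording
requires knowing *where on the head* each source–detector channel sat —
traditionally measured with an electromagnetic 3-D digitizer, which is
slow and unusable with infants. capreg implements the video/photogrammetry
alternative: the cap carries nine solid-color fiducial stickers (three on
the head — nasion Nz and the left/right preauricular points AL/AR — and
six on the cap near Cz, Pz, Iz and the front/left/right cap edges), a
short video is reduced to cropped frames, a structure-from-motion tool
reconstructs a colored 3-D point cloud, and capreg turns that cloud into
per-channel positions in MNI space.

## Method

1. **Frame masking.** Frames are gray-world white-balanced; every
   8-connected cluster of ≥ 5 pixels whose hue lies within ±0.15 of the
   sticker hue (HSV, wrap-around) is a sticker, circled by its exact
   minimum enclosing circle × 1.2; the cap mask (pluggable segmenter,
   hue-band fallback) and a face polygon are added; everything else is
   blackened, and frames more than 98 % blackened are rejected.
2. **Fiducial recovery.** Sticker-colored vertices of the point cloud are
   single-linkage clustered (10 mm radius); cluster centroids are named
   by a RANSAC search: each hypothesis maps an ordered model-label triple
   onto a centroid triple by a closed-form similarity transform and is
   scored by the optimal one-to-one assignment of the remaining model
   fiducials to the remaining centroids; the minimum-cost hypothesis
   fixes the labeling.
3. **Registration and interpolation.** In a one-time pre-registration,
   every probe p_j of the model cap is written as a sum-to-one weighted
   combination of the nine fiducials, p_j = Σᵢ w_ij·f_i (minimum-norm
   least squares). For a subject, the head fiducials (Nz, AL, AR, Cz)
   fix a rotation + translation + anterior–posterior/left–right scaling
   into MNI space, and the same weights applied to the MNI-mapped
   fiducials yield the channel positions. Because each weight row sums
   to one the interpolation commutes with any affine map, and as few as
   five recovered fiducials still determine the channels.
4. **Session statistics.** Per-channel inter/intra-method distances,
   between-session shift vectors, the angle between the two methods'
   shifts, a one-sample Kolmogorov–Smirnov test of those angles against
   uniformity on [0°, 180°], paired t tests, and an OLS regression of one
   method's shift sizes on the other's (F test of the slope, (1, n−2) df).

A synthetic-scene generator (ellipsoidal head, nine stickers at canonical
10-20-like directions, cap rotation + AP/LR scaling, Gaussian vertex
noise, Perlin-patterned cap texture, pinhole-rendered frames) provides
fully ground-truthed inputs, so the whole pipeline is testable without
recordings.

## Worked example

Simulate a subject whose cap is twisted 12° and scaled 1.05/0.97, with
0.5 mm vertex noise, then run the full pipeline on the generated cloud:

```sh
$ capreg simulate --seed 7 --rotation 0 0 12 --scale-ap 1.05 \
    --scale-lr 0.97 --noise-sd 0.5 --out-dir demo/sim
demo/sim
$ capreg run --ply demo/sim/cloud.ply --model demo/sim/model_cap.csv \
    --out-dir demo/out
12 channels -> demo/out/channels_mni.csv
$ head -4 demo/out/channels_mni.csv
channel,x,y,z
CH01,-8.640300774759334,45.0542045966851,55.704207550355896
CH02,3.15335042967485,-39.2658601684545,67.63744725250201
CH03,-56.54430310183535,-16.607653511630488,47.207550545119545
```

The output rows are channel positions in MNI millimetres (x right,
y anterior, z superior). Intermediate artifacts land beside them:
`labeled_fiducials.csv` holds the nine recovered fiducials with the
labeling's residual matching cost, and `pipeline.log` records every
stage's parameters and residuals. `capreg compare-sessions` takes four
channel tables (two sessions × two methods) and writes the shift-size
regression, angle distribution and KS statistic as JSON.

Library use mirrors the CLI: `make_model_head` / `simulate_subject`
generate scenes, `extract_fiducial_clusters` + `label_fiducials` recover
fiducials, `register_model_cap` / `fit_head_transform` /
`project_channels` produce MNI channels, and `capreg.stats` holds the
session analytics.

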