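# Methods

## Registration model

All strategies assume the scene is approximately planar at the sensor
stand-off distance, so the geometric relation between any two bands is a
plane-projective homography: an invertible 3×3 matrix H acting on
homogeneous pixel coordinates [x, y, 1]ᵀ with eight degrees of freedom
(h₃₃ normalized to 1; unit Frobenius norm if |h₃₃| < 1e−8). An affine model
(6 DoF) cannot express the foreshortening caused by the lens offsets, which
is why the full perspective model is used throughout.

The estimation chain is identical for every strategy; only its input images
change:

1. **Keypoints.** SIFT (scikit-image backend) on the single-channel input.
   Binary masks are Gaussian pre-smoothed (σ = 2 px) first: pure {0,1}
   rasters give unstable difference-of-Gaussian extrema. Images are
   min–max normalized to [0,1]; a constant image yields an empty keypoint
   set with a warning.
2. **Matching.** Exhaustive (brute-force) Euclidean nearest and
   second-nearest reference descriptors for each moving descriptor; ties
   broken toward the lower reference index. A single reference keypoint
   produces a +∞ second-best sentinel.
3. **Ratio test.** Keep a pair iff distance / second-best < 0.75, strictly;
   pairs at the threshold and pairs with the +∞ sentinel are discarded.
4. **RANSAC + DLT.** Sample 4 matches (rejecting samples in which any
   source-point triple spans a triangle of area ≤ 1e−6 × squared point
   span), solve the exact minimal homography, and count matches whose
   reprojection distance into the reference frame is ≤ 3.0 px. The
   iteration budget is proportional to the match count,
   N = clamp(10·n, 1000, 20000), and is always exhausted (no early stop);
   hypothesis generation is vectorized in chunks of 1024 (batched 8×8
   solves in globally Hartley-normalized coordinates) so the budget is
   cheap. The hypothesis with most inliers wins, ties broken by lower mean
   inlier residual. The final model is a least-squares DLT on the winning
   inliers, iterated with inlier re-selection until the inlier set is
   stable (≤ 10 rounds); with no outliers this equals the all-points DLT
   exactly. A best consensus below 4 inliers is returned as a flagged
   failure, never an exception.

The DLT itself Hartley-normalizes both point sets (centroid to the origin,
mean distance √2), builds the 2n×9 algebraic system, and takes the right
singular vector of least singular value; minimal 4-point sets are checked
for collinear triples, overdetermined sets for a rank-deficient spectrum.

Warping is inverse-mapped: output(x, y) = input(H⁻¹·[x, y, 1]), bilinear
for intensity images, nearest-neighbour for masks (re-binarized at 0.5),
zero outside the input support. Polygon vertices are mapped analytically by
the same H, preserving vertex order.

Note the deliberate separation of two thresholds that are easy to conflate:
0.75 is a *descriptor-distance ratio* (dimensionless), while the RANSAC
inlier gate is a *geometric* tolerance in pixels (default 3.0). A 0.75-px
geometric gate would be unusably strict for hand-held close-range imagery.

## The five strategies

RedEdge is the fixed reference band (vegetation is brightest in NIR and
RedEdge because chlorophyll is transparent above ~700 nm, which makes both
annotation and matching most reliable there; the choice is configurable).

* **Step A** estimates per-band homographies on the raw band images.
* **Step B (annotation realignment)** applies Step-A homographies to the
  polygon coordinates of each moving band and re-rasterizes; the updated
  annotations can be written back as VIA-compatible JSON (coordinates
  rounded half-away-from-zero).
* **Step C (binary masks)** runs the chain directly on the rasterized
  annotation masks.
* **Step D (masked pixels)** runs it on the raw intensities kept only under
  each band's mask.
* **Predicted branch** unions simulated instance predictions into a
  semantic mask per band, dilates it (disk, radius 2 px by default) so the
  pixels of interest are adequately covered despite prediction tightness,
  and repeats Step C / Step D semantics on the dilated masks. The dilation
  exists to aid registration; the masks carried into evaluation are the
  undilated predictions.

Failed registrations (no keypoints, < 4 ratio-test survivors, no
consensus) flow through flagged: the unregistered mask is scored, so
summary means stay defined and failures remain visible in the record table.

Each branch is scored against its own registration target: the three
ground-truth strategies against the reference-band ground-truth mask, the
predicted strategies against the reference-band predicted mask. Scores are
IoU, cosine-similarity NCC (no mean-centering — a mean-centered Pearson
variant exists under `pearson_ncc` for comparison but is not used by the
benchmark), and non-overlap error defined as the symmetric uncovered
fraction of the union, (FP+FN)/(TP+FP+FN) = 1 − IoU. Empty∧empty IoU is
1.0 by convention (configurable). Aggregations report means, SDs, and
boxplot statistics with 1.5×IQR outliers.

## Synthetic scenes

The generator emulates the statistical structure the pipeline depends on,
not the radiometry of real imagery:

* a textured ground plane (Gaussian-filtered noise, correlation length
  `texture_scale` = 3 px) carrying `n_instances` = 8 lobed blobs (radius
  modulated by a low-order Fourier series; diameters 25–80 px) with their
  own interior speckle — blob interiors must carry texture or masked-pixel
  registration would have nothing to match, a property real canopies
  provide for free;
* per-band foreground/background contrast with a qualitative spectral
  ordering (NIR 3.2, RedEdge 3.0, green 1.8, blue 1.4, red 1.2 over a
  background level of 60 on the 8-bit scale) and additive Gaussian read
  noise (σ = 3);
* per moving band, a random perspective homography H_b whose four corner
  displacements are uniform in ±`warp_magnitude` (default 15 px); the band
  is rendered by resampling the reference-frame layout at H_b x, so
  `true_homographies[b] = H_b` is exact by construction, and band-b
  annotations are the reference polygons mapped through H_b⁻¹ (each band
  annotated in its own geometry, as a careful manual annotator would
  produce). Instances are placed with enough margin to stay in bounds
  under every band's warp, with bounded retries.

Default full-frame size is 960×1280; benchmarks and tests run at 240×320,
where the default warp leaves pre-registration band masks at a mean IoU of
roughly 0.75–0.78 over seeds — misalignment is material but recoverable.
Registration code never reads `true_homographies`; only evaluation does.

**Simulated predictions** stand in for a trained instance-segmentation
network: per instance, dropout with probability 0.05, outline jitter of
2 px (Gaussian vertex noise smoothed along the closed contour with a
correlation length of one sixth of the outline — boundary errors of a
coarse mask head look like broad bulges, not vertex-scale speckle), and a
signed erosion/dilation bias of −1 px (predictions run slightly tight),
with a confidence score that starts at 1.0 and decreases with the realized
perturbation. The random stream restarts per band from the same seed, so
corresponding instances receive the *same* perturbation in every band,
modeling a network making correlated errors on spectrally similar views;
at zero warp the five bands' predictions are therefore identical.

What the generator does **not** capture: real radiometry (no reflectance or
vignetting model), wheat-canopy clutter around the weeds, lens distortion
beyond the homography, annotation error (available as optional jitter but
off by default), and — importantly — band-*independent* prediction errors.
Passing tests therefore demonstrate the correctness and self-consistency of
the registration machinery under known warps, not performance on field
imagery.

## Numerical and design choices

* Coordinates: x = column, y = row, origin top-left, 0-based, pixel centers
  at integers, applied uniformly to polygons, keypoints and homographies.
* Rasterization counts a pixel as foreground iff its center is inside or on
  the polygon boundary (shapely point-in-polygon; self-intersecting jittered
  outlines are repaired with a zero-width buffer); overlapping instances
  union.
* SIFT runs with `upsampling=1` (no initial 2× upscale): about a quarter of
  the classical runtime at a small cost in fine-scale keypoints, which the
  blob scales used here do not need.
* Per-(scene, band, stage) RANSAC seeds derive from the master seed through
  `SeedSequence` spawn keys, so every outcome is bit-reproducible from
  (dataset seed, config, pipeline seed) and no global random state exists.
* Degenerate inputs fail soft where the pipeline must continue (flagged
  outcomes) and loud where a caller error is likely (shape mismatches,
  < 4 correspondences, zero-vector NCC, invalid ratio).

## Known limitations

* Mask-based registration conditions the 8-DoF fit only where mask
  structure exists; when few blobs cover the frame the fitted homography
  extrapolates poorly to the image corners (corner errors of tens of px
  with interior overlap still high). This is intrinsic to registering
  sparse binary masks with a perspective model.
* Because simulated prediction errors are band-correlated (see above), the
  predicted branch loses the largest real-world driver of degradation
  relative to ground-truth masks. Its mean IoU consequently sits only
  slightly below the ground-truth counterparts, and for the binary-mask
  pair the ordering can invert for occasional dataset seeds where
  ground-truth mask registration draws a heavy-tailed scene. The
  masked-pixel pair is stable across seeds.
* NCC as implemented (cosine similarity of non-negative rasters) is
  bounded well away from 0 for overlapping masks and therefore compresses
  differences; it is reported for completeness, IoU is the informative
  score.
* The benchmark's absolute IoU/NCC levels on synthetic scenes are higher
  than anything achievable on real field imagery (no canopy clutter, exact
  annotations, planar world); only orderings and sensitivities should be
  read from them.
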