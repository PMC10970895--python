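# msreg — multispectral band co-registration with SIFT and RANSAC

Close-range multispectral cameras (e.g. a five-band MicaSense RedEdge-M held
~1 m above a crop canopy) capture each spectral channel through a separate
lens, so the blue, green, red, NIR and RedEdge images of one scene are
mutually misaligned by small perspective distortions. Any pixel-level
analysis that combines bands — such as segmenting broad-leaved weeds
(*Raphanus raphanistrum*) among wheat — first needs the bands co-registered.

`msreg` implements and evaluates three feature-based registration
strategies, all built on the same chain — SIFT keypoints, exhaustive
descriptor matching, Lowe's ratio test (threshold 0.75), and a homography
H ∈ ℝ³ˣ³ (8 degrees of freedom, h₃₃ = 1) estimated by the direct linear
transform inside RANSAC — differing only in *what* is matched against the
RedEdge reference band:

* **annotation realignment** — estimate H on the raw band images, then warp
  the polygon annotation coordinates (x, y) ↦ ((h₁₁x+h₁₂y+h₁₃)/w,
  (h₂₁x+h₂₂y+h₂₃)/w), w = h₃₁x+h₃₂y+h₃₃, and re-rasterize;
* **binary masks** — register the {0,1} annotation masks themselves;
* **masked pixels** — register only the raw intensities kept under the mask.

A predicted branch repeats the last two on simulated imperfect instance
predictions (dilated before registration). Quality is scored per
(scene, band, strategy) with IoU = |A∩B| / |A∪B|, the normalized coefficient
of correlation NCC = i₁ᵀi₂ / (‖i₁‖‖i₂‖) on flattened rasters, and the
non-overlap error 1 − IoU; instance predictions are additionally scored with
precision/recall/F1 and mask-level AP. A seeded synthetic-scene generator
(textured ground plane, lobed plant-like blobs, per-band contrast, known
ground-truth inter-band homographies) makes the whole pipeline testable
end-to-end.

## Worked example

```python
from msreg import (
    Band, MOVING_BANDS, REFERENCE_BAND, SceneSpec,
    generate_scene, rasterize, step_a_homographies,
    step_b_realign_annotations, iou,
)

spec = SceneSpec(shape=(240, 320), seed=0)
scene, annotations = generate_scene(spec)
masks = {b: rasterize(annotations[b], spec.shape) for b in Band}

results = step_a_homographies(scene, seed=0)          # Step A: estimate H per band
_, realigned, _ = step_b_realign_annotations(scene, annotations, results)
for band in MOVING_BANDS:
    before = iou(masks[band], masks[REFERENCE_BAND])
    after = iou(realigned[band], masks[REFERENCE_BAND])
    err = results[band].homography.corner_error(
        scene.true_homographies[band], spec.shape
    )
    print(f"{band.value:>5}: IoU {before:.3f} -> {after:.3f}  "
          f"(corner error vs truth {err:.2f} px, {results[band].n_inliers} inliers)")
```

prints

```
 blue: IoU 0.807 -> 0.994  (corner error vs truth 0.86 px, 126 inliers)
green: IoU 0.799 -> 0.997  (corner error vs truth 0.55 px, 196 inliers)
  red: IoU 0.847 -> 0.994  (corner error vs truth 1.01 px, 98 inliers)
  nir: IoU 0.687 -> 0.996  (corner error vs truth 0.31 px, 224 inliers)
```

The interpretation: before registration the per-band annotation masks
overlap the RedEdge mask at IoU 0.69–0.85 (material inter-sensor parallax);
after realigning the annotations with the estimated homographies the overlap
rises above 0.99, and each estimated homography agrees with the generator's
ground-truth warp to about a pixel at the image corners.

## Command line

```sh
msreg simulate  --out data/ --seed 0 --n-scenes 4        # scenes + VIA JSON + truth
msreg register  data/scene_000 --strategy C --seed 0     # one scene, one strategy
msreg benchmark --out results/ --seed 0 --n-scenes 16    # all five strategies
```

`benchmark` writes the per-(scene, band, strategy) record CSV plus
per-strategy and per-band summary tables; runs are bit-reproducible given
the seed.

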