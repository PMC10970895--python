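"""The registration strategies, orchestrated per scene against the RedEdge band.

Five strategies are benchmarked, all sharing the same SIFT + ratio test +
RANSAC/DLT estimation chain and differing only in *what* is matched:

* ``annotation_realignment`` (Step B) — homographies estimated on the raw
  band images (Step A) are applied to the polygon annotation coordinates,
  and masks are re-rasterized from the realigned polygons.
* ``binary_mask`` (Step C) — the binary ground-truth masks themselves are
  registered (keypoints on Gaussian-smoothed masks).
* ``masked_pixels`` (Step D) — the raw intensities kept only under the mask
  are registered.
* ``predicted_binary_mask`` / ``predicted_masked_pixels`` — Step C / Step D
  semantics applied to dilated *predicted* instance masks instead of ground
  truth.

Every outcome is scored against the reference-band ground-truth mask with
IoU, NCC and the non-overlap error.  Failed registrations (too few
keypoints or no consensus) are carried through flagged, scored on the
unregistered mask, so summary means remain defined.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .geometry import (
    Homography,
    RansacParams,
    RansacResult,
    SiftParams,
    detect_keypoints,
    dilate,
    estimate_homography_ransac,
    match_descriptors,
    ratio_filter,
    warp_image,
    warp_mask,
    warp_polygon,
)
from .metrics import MetricsTable, aggregate
from .scene_io import (
    MOVING_BANDS,
    REFERENCE_BAND,
    AnnotationSet,
    Band,
    PolygonRegion,
    Scene,
    apply_mask,
    rasterize,
)
from .synthetic_data import PredictionSpec, simulate_predictions

logger = logging.getLogger(__name__)

__all__ = [
    "Strategy",
    "PipelineConfig",
    "RegistrationOutcome",
    "register_pair",
    "step_a_homographies",
    "step_b_realign_annotations",
    "step_c_register_masks",
    "step_d_register_masked_pixels",
    "predicted_branch",
    "run_benchmark",
]


class Strategy(enum.Enum):
    ANNOTATION_REALIGNMENT = "annotation_realignment"
    BINARY_MASK = "binary_mask"
    MASKED_PIXELS = "masked_pixels"
    PREDICTED_BINARY_MASK = "predicted_binary_mask"
    PREDICTED_MASKED_PIXELS = "predicted_masked_pixels"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class PipelineConfig:
    """Everything tunable about the estimation chain, with its defaults:
    Lowe ratio 0.75, RANSAC inlier gate 3 px, dilation radius 2 px (disk)
    for the predicted branch, RedEdge as the reference band."""

    sift: SiftParams = field(default_factory=SiftParams)
    ransac: RansacParams = field(default_factory=RansacParams)
    ratio: float = 0.75
    dilation_radius: int = 2
    reference_band: Band = REFERENCE_BAND


@dataclass
class RegistrationOutcome:
    scene_id: str
    band: Band
    strategy: Strategy
    homography_used: Optional[Homography]
    registered_mask: np.ndarray
    registered_image: Optional[np.ndarray] = None
    n_inliers: int = 0
    status: str = "ok"  # "ok" | "failed"

    @property
    def failed(self) -> bool:
        return self.status != "ok"


def _derive_seed(seed: int, *key: int) -> int:
    """Stable per-(scene, band, stage) RANSAC seed below 2**31."""
    return int(
        np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )


def register_pair(
    moving: np.ndarray,
    reference: np.ndarray,
    config: PipelineConfig,
    seed: int,
    is_mask: bool = False,
    reference_kps=None,
) -> RansacResult:
    """Full estimation chain for one image pair: SIFT keypoints on both,
    brute-force matching, Lowe ratio filter, RANSAC + DLT.

    Returns a failed :class:`~msreg.geometry.RansacResult` (never raises) when
    either image yields too few keypoints or no consensus is found.
    ``reference_kps`` allows reuse of the reference detection across bands.
    """

    def _fail() -> RansacResult:
        return RansacResult(
            homography=None,
            inlier_indices=np.zeros(0, dtype=int),
            n_iterations_run=0,
            residuals=np.zeros(0),
            success=False,
        )

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        mov_kps = detect_keypoints(moving, config.sift, is_mask=is_mask)
        ref_kps = (
            reference_kps
            if reference_kps is not None
            else detect_keypoints(reference, config.sift, is_mask=is_mask)
        )
    if len(mov_kps) == 0 or len(ref_kps) == 0:
        return _fail()
    matches = ratio_filter(match_descriptors(mov_kps, ref_kps), config.ratio)
    if len(matches) < 4:
        return _fail()
    return estimate_homography_ransac(
        matches, mov_kps, ref_kps, config.ransac, seed=seed
    )


def step_a_homographies(
    scene: Scene, config: PipelineConfig | None = None, seed: int = 0
) -> dict[Band, RansacResult]:
    """Step A: estimate, for each moving band, the homography taking that
    band's raw image into the reference (RedEdge) frame."""
    if config is None:
        config = PipelineConfig()
    ref_img = scene.images[config.reference_band]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        ref_kps = detect_keypoints(ref_img, config.sift)
    results: dict[Band, RansacResult] = {}
    for i, band in enumerate(MOVING_BANDS):
        results[band] = register_pair(
            scene.images[band],
            ref_img,
            config,
            seed=_derive_seed(seed, 0, i),
            reference_kps=ref_kps if len(ref_kps) else None,
        )
        if not results[band].success:
            logger.warning(
                "scene %s band %s: Step A registration failed", scene.scene_id, band
            )
    return results


def step_b_realign_annotations(
    scene: Scene,
    annotations: AnnotationSet,
    homographies: dict[Band, RansacResult | Homography],
) -> tuple[AnnotationSet, dict[Band, np.ndarray], dict[Band, str]]:
    """Step B: warp every moving-band polygon by that band's homography and
    re-rasterize.

    Reference-band annotations are untouched.  A band whose homography is
    unavailable (failed Step A) passes its polygons through unwarped and is
    flagged.  Returns (updated annotations, per-band masks, per-band status).
    """
    shape = annotations.source_image_shape
    new_regions: dict[Band, list[PolygonRegion]] = {
        REFERENCE_BAND: list(annotations[REFERENCE_BAND])
    }
    masks: dict[Band, np.ndarray] = {
        REFERENCE_BAND: rasterize(annotations[REFERENCE_BAND], shape)
    }
    status: dict[Band, str] = {REFERENCE_BAND: "ok"}
    for band in MOVING_BANDS:
        h = homographies.get(band)
        if isinstance(h, RansacResult):
            h = h.homography if h.success else None
        if h is None:
            new_regions[band] = list(annotations[band])
            status[band] = "failed"
        else:
            new_regions[band] = [warp_polygon(r, h) for r in annotations[band]]
            status[band] = "ok"
        masks[band] = rasterize(new_regions[band], shape)
    updated = AnnotationSet(regions=new_regions, source_image_shape=shape)
    return updated, masks, status


def _outcome_from_result(
    scene_id: str,
    band: Band,
    strategy: Strategy,
    result: RansacResult,
    moving_mask: np.ndarray,
    shape: tuple[int, int],
    registered_image: np.ndarray | None = None,
) -> RegistrationOutcome:
    if result.success and result.homography is not None:
        return RegistrationOutcome(
            scene_id=scene_id,
            band=band,
            strategy=strategy,
            homography_used=result.homography,
            registered_mask=warp_mask(moving_mask, result.homography, shape),
            registered_image=registered_image,
            n_inliers=result.n_inliers,
            status="ok",
        )
    # failed: carry the unregistered mask through, flagged
    return RegistrationOutcome(
        scene_id=scene_id,
        band=band,
        strategy=strategy,
        homography_used=None,
        registered_mask=np.array(moving_mask, copy=True),
        registered_image=None,
        n_inliers=0,
        status="failed",
    )


def step_c_register_masks(
    moving_masks: dict[Band, np.ndarray],
    reference_mask: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
    scene_id: str = "",
    strategy: Strategy = Strategy.BINARY_MASK,
    eval_masks: dict[Band, np.ndarray] | None = None,
) -> dict[Band, RegistrationOutcome]:
    """Step C: register each band's binary mask directly to the reference mask.

    Keypoints are detected on Gaussian-smoothed masks; the estimated
    homography then warps the moving mask (nearest-neighbour) into the
    reference frame.  Masks with too little structure fail gracefully.

    ``eval_masks`` optionally supplies a different per-band mask to warp into
    the outcome than the one driving the registration (the predicted branch
    registers *dilated* masks but reports the undilated predictions).
    """
    if config is None:
        config = PipelineConfig()
    shape = reference_mask.shape
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        ref_kps = detect_keypoints(
            reference_mask.astype(float) * 255, config.sift, is_mask=True
        )
    out: dict[Band, RegistrationOutcome] = {}
    for i, band in enumerate(MOVING_BANDS):
        mask = moving_masks[band]
        result = register_pair(
            mask.astype(float) * 255,
            reference_mask.astype(float) * 255,
            config,
            seed=_derive_seed(seed, 1, i),
            is_mask=True,
            reference_kps=ref_kps if len(ref_kps) else None,
        )
        carried = eval_masks[band] if eval_masks is not None else mask
        out[band] = _outcome_from_result(
            scene_id, band, strategy, result, carried, shape
        )
        if out[band].failed:
            logger.warning("scene %s band %s: %s failed", scene_id, band, strategy)
    return out


def step_d_register_masked_pixels(
    scene: Scene,
    masks: dict[Band, np.ndarray],
    reference_mask: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
    strategy: Strategy = Strategy.MASKED_PIXELS,
    eval_masks: dict[Band, np.ndarray] | None = None,
) -> dict[Band, RegistrationOutcome]:
    """Step D: register only the pixels of interest.

    Each band's raw intensities are masked to the annotated pixels and the
    estimation chain runs on these masked intensity images.  Both the masked
    image (bilinear) and its mask (nearest) are warped into the reference
    frame.  ``eval_masks`` behaves as in :func:`step_c_register_masks`.
    """
    if config is None:
        config = PipelineConfig()
    shape = reference_mask.shape
    ref_masked = apply_mask(scene.images[config.reference_band], reference_mask)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        ref_kps = detect_keypoints(ref_masked, config.sift)
    out: dict[Band, RegistrationOutcome] = {}
    for i, band in enumerate(MOVING_BANDS):
        mask = masks[band]
        mov_masked = apply_mask(scene.images[band], mask)
        result = register_pair(
            mov_masked,
            ref_masked,
            config,
            seed=_derive_seed(seed, 2, i),
            reference_kps=ref_kps if len(ref_kps) else None,
        )
        registered_image = (
            warp_image(mov_masked, result.homography, shape)
            if result.success
            else None
        )
        carried = eval_masks[band] if eval_masks is not None else mask
        out[band] = _outcome_from_result(
            scene.scene_id, band, strategy, result, carried, shape, registered_image
        )
        if out[band].failed:
            logger.warning(
                "scene %s band %s: %s failed", scene.scene_id, band, strategy
            )
    return out


def predicted_branch(
    scene: Scene,
    predicted_masks: dict[Band, list[tuple[np.ndarray, float]]],
    config: PipelineConfig | None = None,
    seed: int = 0,
    dilation_radius: int | None = None,
) -> tuple[dict[Strategy, dict[Band, RegistrationOutcome]], dict[Band, np.ndarray]]:
    """Run Step C and Step D semantics on *predicted* instance masks.

    Per band, the predicted instance masks are unioned into a semantic mask
    and morphologically dilated (disk, default radius from the config) so
    that the pixels of interest are adequately covered despite prediction
    tightness.  The *dilated* masks drive the registration (Step C keypoints
    / Step D pixel masking); the outcome masks carried for evaluation are
    the undilated predictions, registration being the thing under test, not
    the dilation.  Returns the per-strategy outcomes together with the
    undilated semantic prediction masks (the reference-band entry is this
    branch's evaluation target).
    """
    if config is None:
        config = PipelineConfig()
    if dilation_radius is None:
        dilation_radius = config.dilation_radius
    shape = scene.shape
    semantic: dict[Band, np.ndarray] = {}
    dilated: dict[Band, np.ndarray] = {}
    for band in Band:
        preds = predicted_masks.get(band, [])
        m = np.zeros(shape, dtype=np.uint8)
        for pm, _score in preds:
            np.logical_or(m, pm, out=m)
        semantic[band] = m.astype(np.uint8)
        dilated[band] = dilate(semantic[band], dilation_radius)
        if dilated[band].all():
            logger.warning(
                "scene %s band %s: dilation merged every instance into one "
                "foreground region",
                scene.scene_id,
                band,
            )
    ref_mask = dilated[config.reference_band]
    c_out = step_c_register_masks(
        dilated,
        ref_mask,
        config,
        seed=_derive_seed(seed, 3),
        scene_id=scene.scene_id,
        strategy=Strategy.PREDICTED_BINARY_MASK,
        eval_masks=semantic,
    )
    d_out = step_d_register_masked_pixels(
        scene,
        dilated,
        ref_mask,
        config,
        seed=_derive_seed(seed, 4),
        strategy=Strategy.PREDICTED_MASKED_PIXELS,
        eval_masks=semantic,
    )
    return (
        {
            Strategy.PREDICTED_BINARY_MASK: c_out,
            Strategy.PREDICTED_MASKED_PIXELS: d_out,
        },
        semantic,
    )


def _score_outcome(
    outcome: RegistrationOutcome, reference_mask: np.ndarray
) -> dict:
    m = outcome.registered_mask
    try:
        ncc_val = _metrics.ncc(m, reference_mask)
    except _metrics.UndefinedMetricError:
        ncc_val = float("nan")
    iou_val = _metrics.iou(m, reference_mask)
    return {
        "scene_id": outcome.scene_id,
        "band": outcome.band.value,
        "strategy": outcome.strategy.value,
        "iou": iou_val,
        "ncc": ncc_val,
        "nonoverlap_error": 1.0 - iou_val,
        "n_inliers": outcome.n_inliers,
        "failed": outcome.failed,
    }


def run_benchmark(
    dataset: list[tuple[Scene, AnnotationSet]],
    config: PipelineConfig | None = None,
    seed: int = 0,
    prediction_spec: PredictionSpec | None = None,
    strategies: list[Strategy] | None = None,
) -> MetricsTable:
    """Execute the registration strategies on every scene and aggregate.

    For each scene: ground-truth masks are rasterized per band; Step A
    estimates raw-image homographies feeding Step B; Steps C and D register
    ground-truth masks and masked pixels; the predicted branch repeats C/D on
    simulated predictions.  Every (scene, band, strategy) cell is scored
    against the reference-band ground-truth mask.  Deterministic given
    ``seed`` (which also seeds the prediction simulator unless a
    ``prediction_spec`` is supplied).
    """
    if not dataset:
        raise ValueError("benchmark needs at least one scene")
    if config is None:
        config = PipelineConfig()
    if strategies is None:
        strategies = list(Strategy)

    records: list[dict] = []
    for s_idx, (scene, annotations) in enumerate(dataset):
        shape = scene.shape
        gt_masks = {b: rasterize(annotations[b], shape) for b in Band}
        ref_gt = gt_masks[config.reference_band]
        scene_seed = _derive_seed(seed, 10, s_idx)

        need_a = Strategy.ANNOTATION_REALIGNMENT in strategies
        if need_a:
            a_results = step_a_homographies(scene, config, seed=scene_seed)
            _, b_masks, b_status = step_b_realign_annotations(
                scene, annotations, a_results
            )
            for band in MOVING_BANDS:
                rec = _score_outcome(
                    RegistrationOutcome(
                        scene_id=scene.scene_id,
                        band=band,
                        strategy=Strategy.ANNOTATION_REALIGNMENT,
                        homography_used=(
                            a_results[band].homography
                            if a_results[band].success
                            else None
                        ),
                        registered_mask=b_masks[band],
                        n_inliers=a_results[band].n_inliers,
                        status=b_status[band],
                    ),
                    ref_gt,
                )
                records.append(rec)

        if Strategy.BINARY_MASK in strategies:
            c_out = step_c_register_masks(
                gt_masks,
                ref_gt,
                config,
                seed=scene_seed,
                scene_id=scene.scene_id,
            )
            records += [_score_outcome(c_out[b], ref_gt) for b in MOVING_BANDS]

        if Strategy.MASKED_PIXELS in strategies:
            d_out = step_d_register_masked_pixels(
                scene, gt_masks, ref_gt, config, seed=scene_seed
            )
            records += [_score_outcome(d_out[b], ref_gt) for b in MOVING_BANDS]

        if (
            Strategy.PREDICTED_BINARY_MASK in strategies
            or Strategy.PREDICTED_MASKED_PIXELS in strategies
        ):
            pspec = prediction_spec or PredictionSpec(seed=_derive_seed(seed, 20, s_idx))
            preds = simulate_predictions(annotations, pspec)
            pred_out, pred_semantic = predicted_branch(
                scene, preds, config, seed=scene_seed
            )
            # the predicted branch registers *to* the predicted reference
            # mask, so that mask is its evaluation target
            ref_pred = pred_semantic[config.reference_band]
            for strat, per_band in pred_out.items():
                if strat in strategies:
                    records += [
                        _score_outcome(per_band[b], ref_pred) for b in MOVING_BANDS
                    ]

    return aggregate(pd.DataFrame.from_records(records))
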