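"""Seeded generator of synthetic multiband scenes, annotations and predictions.

The generator emulates the statistical structure of close-range five-band
agricultural imagery: a textured ground plane carrying a handful of
plant-like bright blobs, imaged by five co-scened sensors whose viewpoints
differ by small perspective homographies (inter-sensor parallax at ~1 m
stand-off).  Vegetation contrast varies by band — brightest in NIR and
RedEdge, faintest in red — and every band carries its own polygon
annotations expressed in its own pixel geometry.

Blob interiors carry band-correlated speckle texture: masked-pixel
registration needs intensity features inside the masks, a property the real
imagery provides for free but flat synthetic blobs would not.

Every scene records its true inter-band homographies, which the *evaluation*
code may consult as an exact oracle; registration code never sees them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Homography, dilate, erode, estimate_homography_dlt
from .scene_io import (
    MOVING_BANDS,
    REFERENCE_BAND,
    AnnotationSet,
    Band,
    PolygonRegion,
    Scene,
    rasterize,
)

__all__ = [
    "SceneSpec",
    "PredictionSpec",
    "generate_scene",
    "generate_dataset",
    "simulate_predictions",
]

#: Foreground/background intensity ratio per band: a qualitative ordering
#: only (NIR/RedEdge highest, red lowest), not a reflectance model.
DEFAULT_BAND_CONTRAST = {
    Band.BLUE: 1.4,
    Band.GREEN: 1.8,
    Band.RED: 1.2,
    Band.NIR: 3.2,
    Band.REDEDGE: 3.0,
}

_BACKGROUND_LEVEL = 60.0  # mean soil intensity, 8-bit scale
_TEXTURE_AMPLITUDE = 0.18  # relative speckle amplitude, fore- and background


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``shape`` defaults to the full 960x1280 sensor raster; benchmarks and
    tests run at 240x320 for speed.  ``instance_scale_px`` is the blob
    diameter range; ``warp_magnitude`` bounds the per-corner displacement of
    each inter-band homography in pixels; ``noise_sd`` is additive Gaussian
    read noise on the 8-bit scale.
    """

    shape: tuple[int, int] = (960, 1280)
    n_instances: int = 8
    instance_scale_px: tuple[float, float] = (25.0, 80.0)
    band_contrast: dict[Band, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_CONTRAST)
    )
    warp_magnitude: float = 15.0
    noise_sd: float = 3.0
    texture_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 0 or self.warp_magnitude < 0 or self.noise_sd < 0:
            raise ValueError("spec magnitudes must be nonnegative")
        if self.instance_scale_px[0] <= 0:
            raise ValueError("instance scale must be positive")


@dataclass
class PredictionSpec:
    """Imperfection model for simulated instance predictions.

    Stands in for a trained instance-segmentation network: whole instances
    are missed with ``dropout_prob``; surviving outlines are vertex-jittered
    by ``boundary_jitter_px`` (Gaussian sd); ``erosion_dilation_bias`` shifts
    the boundary by a signed radius (negative = predictions run tight).
    """

    dropout_prob: float = 0.05
    boundary_jitter_px: float = 2.0
    erosion_dilation_bias: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must lie in [0, 1]")


def _blob_polygon(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n_vertices: int = 24,
) -> np.ndarray:
    """A smooth star-shaped polygon: radius modulated by a low-order Fourier
    series around a circle (plant-canopy-like lobed outline)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones(n_vertices)
    for k in (1, 2, 3):
        amp = rng.uniform(0, 0.25 / k)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.3, None) * radius
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _random_homography(
    rng: np.random.Generator, shape: tuple[int, int], magnitude: float
) -> Homography:
    """Perspective map (moving -> reference) whose corner displacements are
    bounded by ``magnitude`` pixels."""
    h, w = shape
    ref_corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
    )
    delta = rng.uniform(-magnitude, magnitude, size=(4, 2))
    moving_corners = ref_corners + delta
    if magnitude == 0:
        return Homography.identity()
    return estimate_homography_dlt(moving_corners, ref_corners)


def _in_bounds(vertices: np.ndarray, shape: tuple[int, int], margin: float) -> bool:
    h, w = shape
    return bool(
        (vertices[:, 0] >= margin).all()
        and (vertices[:, 0] <= w - 1 - margin).all()
        and (vertices[:, 1] >= margin).all()
        and (vertices[:, 1] <= h - 1 - margin).all()
    )


def generate_scene(spec: SceneSpec) -> tuple[Scene, AnnotationSet]:
    """Generate one five-band scene with per-band annotations and true warps.

    Layout and textures are built once in the reference (RedEdge) frame.
    Each moving band b draws a bounded perspective homography H_b (mapping
    band-b pixel coordinates into reference coordinates) and is rendered by
    resampling the reference-frame layout at H_b x, so the recorded
    ``true_homographies[b] = H_b`` is exact by construction.  Band-b
    annotations are the reference polygons mapped through H_b^-1 — each band
    annotated in its own geometry, as a careful manual annotator would.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    # inter-band warps, one per moving band
    homographies = {
        b: _random_homography(rng, spec.shape, spec.warp_magnitude)
        for b in MOVING_BANDS
    }

    # reference-frame blob layout; instances must stay inside every band
    max_r = spec.instance_scale_px[1] / 2
    polys: list[np.ndarray] = []
    for _ in range(spec.n_instances):
        for attempt in range(200):
            radius = rng.uniform(*spec.instance_scale_px) / 2
            margin = radius * 1.3 + spec.warp_magnitude + 3
            if 2 * margin >= min(h, w):
                raise ValueError(
                    "instances cannot fit inside the raster under the warp; "
                    "reduce instance_scale_px or warp_magnitude"
                )
            center = np.array(
                [rng.uniform(margin, w - 1 - margin), rng.uniform(margin, h - 1 - margin)]
            )
            verts = _blob_polygon(rng, center, radius)
            ok = _in_bounds(verts, spec.shape, 1.0) and all(
                _in_bounds(hb.inverse().apply(verts), spec.shape, 1.0)
                for hb in homographies.values()
            )
            if ok:
                polys.append(verts)
                break
        else:
            raise RuntimeError("could not place an instance after 200 retries")

    ref_regions = [
        PolygonRegion(xs=v[:, 0], ys=v[:, 1], instance_id=i)
        for i, v in enumerate(polys)
    ]

    # shared textures: band-correlated speckle, unit-sd after smoothing
    def _texture() -> np.ndarray:
        t = gaussian_filter(rng.standard_normal(spec.shape), spec.texture_scale)
        sd = t.std()
        return t / sd if sd > 0 else t

    t_fg = _texture()
    t_bg = _texture()

    fg = rasterize(ref_regions, spec.shape).astype(float)
    fg_soft = gaussian_filter(fg, 1.0)

    # per-band reference-frame layouts (float), then warp + noise per band
    images: dict[Band, np.ndarray] = {}
    noise = {b: rng.standard_normal(spec.shape) * spec.noise_sd for b in Band}
    for band in Band:
        ratio = spec.band_contrast[band]
        bg_level = _BACKGROUND_LEVEL
        fg_level = min(ratio * bg_level, 252.0)
        layout = (1 - fg_soft) * bg_level * (1 + _TEXTURE_AMPLITUDE * t_bg) + (
            fg_soft
        ) * fg_level * (1 + _TEXTURE_AMPLITUDE * t_fg)
        if band is REFERENCE_BAND:
            warped = layout
        else:
            # band(x) = layout(H_b x): resample the reference layout at H_b x
            from skimage.transform import ProjectiveTransform, warp

            warped = warp(
                layout,
                ProjectiveTransform(matrix=homographies[band].matrix),
                order=1,
                cval=0.0,
                preserve_range=True,
            )
        images[band] = np.clip(warped + noise[band], 0, 255).astype(np.uint8)

    regions = {REFERENCE_BAND: ref_regions}
    for band in MOVING_BANDS:
        hb_inv = homographies[band].inverse()
        regions[band] = [
            PolygonRegion(
                xs=hb_inv.apply(r.vertices)[:, 0],
                ys=hb_inv.apply(r.vertices)[:, 1],
                instance_id=r.instance_id,
            )
            for r in ref_regions
        ]

    scene = Scene(
        scene_id=f"synthetic_{spec.seed}",
        images=images,
        true_homographies=homographies,
    )
    annotations = AnnotationSet(regions=regions, source_image_shape=spec.shape)
    return scene, annotations


def generate_dataset(
    n_scenes: int, spec: SceneSpec, master_seed: int
) -> list[tuple[Scene, AnnotationSet]]:
    """Generate a dataset of independent scenes.

    Per-scene seeds derive from ``master_seed`` through a counter-based
    splitting rule (``SeedSequence(master_seed, spawn_key=(i,))``), so scenes
    are statistically independent yet the whole dataset is reproducible from
    the single master seed.
    """
    out = []
    for i in range(n_scenes):
        seed_i = int(
            np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        scene, ann = generate_scene(dataclasses.replace(spec, seed=seed_i))
        scene.scene_id = f"scene_{i:03d}"
        out.append((scene, ann))
    return out


def simulate_predictions(
    annotations: AnnotationSet,
    pspec: PredictionSpec,
) -> dict[Band, list[tuple[np.ndarray, float]]]:
    """Simulate imperfect instance predictions from ground-truth annotations.

    Per band and instance: drop the instance with ``dropout_prob``; otherwise
    jitter the outline vertices with Gaussian noise, rasterize, and apply the
    signed erosion/dilation bias.  The confidence score starts at 1.0 and
    decreases with the realized perturbation magnitude, so unperturbed
    predictions score exactly 1.0.  Deterministic given ``pspec.seed``.

    The random stream restarts from the same seed for every band, so the
    *same* perturbations hit corresponding instances across bands — modeling
    a network that makes correlated errors on spectrally similar views of
    the same plants.  On a zero-warp scene this makes the five bands'
    predictions identical.
    """
    shape = annotations.source_image_shape
    out: dict[Band, list[tuple[np.ndarray, float]]] = {}
    for band in Band:
        if band not in annotations.regions:
            continue
        rng = np.random.default_rng(pspec.seed)
        preds: list[tuple[np.ndarray, float]] = []
        for region in annotations[band]:
            if rng.uniform() < pspec.dropout_prob:
                continue
            n_v = len(region.xs)
            if pspec.boundary_jitter_px > 0:
                # Gaussian vertex noise smoothed along the closed outline
                # (correlation length ~ 1/6 of the contour): prediction
                # boundary errors of a coarse mask head look like broad
                # bulges of a mis-traced contour, not vertex-scale speckle
                white = rng.normal(0, 1.0, size=(n_v, 2))
                sigma_ring = max(n_v / 6.0, 0.5)
                half = min(int(3 * sigma_ring), n_v)
                kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_ring) ** 2)
                kernel /= kernel.sum()
                jitter = np.empty_like(white)
                for k in range(2):
                    padded = np.concatenate(
                        [white[-half:, k], white[:, k], white[:half, k]]
                    ) if half else white[:, k]
                    jitter[:, k] = np.convolve(padded, kernel, mode="valid")
                sd = jitter.std()
                if sd > 0:
                    jitter *= pspec.boundary_jitter_px / sd
            else:
                jitter = np.zeros((n_v, 2))
            verts = region.vertices + jitter
            mask = rasterize(
                [PolygonRegion(verts[:, 0], verts[:, 1], region.instance_id)],
                shape,
            )
            bias = pspec.erosion_dilation_bias
            if bias > 0:
                mask = dilate(mask, bias)
            elif bias < 0:
                mask = erode(mask, -bias)
            realized = float(np.abs(jitter).mean())
            score = float(np.clip(1.0 - 0.03 * realized - 0.04 * abs(bias), 0.05, 1.0))
            preds.append((mask, score))
        out[band] = preds
    return out
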