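"""Multispectral scene data model, VIA-style annotation I/O, and rasterization.

A *scene* is one camera station: five single-channel 8-bit images (blue,
green, red, near-infrared, RedEdge) of the same ground plane, captured by
separate lenses and therefore geometrically misaligned by small perspective
homographies.  Annotations are polygon outlines of weed instances, stored in
the VGG Image Annotator (VIA) project-JSON dialect with ``all_points_x`` /
``all_points_y`` coordinate lists.

Coordinate convention, applied uniformly across the package: x = column,
y = row, origin at the top-left corner, 0-based, pixel centers at integer
coordinates.
"""

from __future__ import annotations

import enum
import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Band",
    "REFERENCE_BAND",
    "MOVING_BANDS",
    "PolygonRegion",
    "AnnotationSet",
    "Scene",
    "ensure_binary_mask",
    "read_via_json",
    "write_via_json",
    "rasterize",
    "rasterize_instances",
    "apply_mask",
]


class Band(enum.Enum):
    """The five spectral channels of a MicaSense RedEdge-M style sensor."""

    BLUE = "blue"
    GREEN = "green"
    RED = "red"
    NIR = "nir"
    REDEDGE = "rededge"

    @property
    def nominal_wavelength_nm(self) -> int:
        return _WAVELENGTHS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_WAVELENGTHS = {
    Band.BLUE: 475,
    Band.GREEN: 560,
    Band.RED: 668,
    Band.NIR: 840,
    Band.REDEDGE: 717,
}

#: RedEdge is the designated reference band for every registration strategy:
#: vegetation is brightest in NIR/RedEdge (chlorophyll is transparent above
#: ~700 nm), which makes annotation and matching most reliable there.
REFERENCE_BAND = Band.REDEDGE

#: The four bands registered *to* the reference.
MOVING_BANDS = (Band.BLUE, Band.GREEN, Band.RED, Band.NIR)


class ViaFormatError(ValueError):
    """Raised for malformed VIA JSON (missing/unequal polygon coordinate lists)."""


class BandPatternError(ValueError):
    """Raised when a band token cannot be resolved from an image filename."""


@dataclass
class PolygonRegion:
    """One polygon annotation: paired x/y vertex lists and an instance label."""

    xs: np.ndarray
    ys: np.ndarray
    instance_id: int = 0

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if self.xs.ndim != 1 or self.ys.ndim != 1:
            raise ValueError("polygon coordinates must be 1-D sequences")
        if len(self.xs) != len(self.ys):
            raise ViaFormatError(
                f"region {self.instance_id}: all_points_x has {len(self.xs)} "
                f"entries but all_points_y has {len(self.ys)}"
            )
        if len(self.xs) < 3:
            raise ViaFormatError(
                f"region {self.instance_id}: polygon needs >= 3 vertices"
            )
        if not (np.isfinite(self.xs).all() and np.isfinite(self.ys).all()):
            raise ValueError(f"region {self.instance_id}: non-finite coordinate")

    @property
    def vertices(self) -> np.ndarray:
        """(n, 2) array of (x, y) vertices."""
        return np.column_stack([self.xs, self.ys])

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass
class AnnotationSet:
    """Per-band polygon annotations for one scene.

    Each band carries its own region list: every band is annotated in its own
    pixel geometry, as a manual per-band annotation workflow would produce.
    """

    regions: dict[Band, list[PolygonRegion]]
    source_image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        for band, regs in self.regions.items():
            ids = [r.instance_id for r in regs]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate instance_id within band {band}")

    def bands(self) -> list[Band]:
        return list(self.regions)

    def __getitem__(self, band: Band) -> list[PolygonRegion]:
        return self.regions[band]


@dataclass
class Scene:
    """Five co-scened band images plus, for synthetic scenes, the true warps.

    ``true_homographies`` maps each *moving* band to the homography taking
    that band's pixel coordinates into reference-band coordinates.  It exists
    only for simulated scenes and is consulted exclusively by evaluation code.
    """

    scene_id: str
    images: dict[Band, np.ndarray]
    true_homographies: Optional[dict[Band, "Homography"]] = None  # noqa: F821

    def __post_init__(self) -> None:
        missing = [b for b in Band if b not in self.images]
        if missing:
            raise ValueError(f"scene {self.scene_id}: missing bands {missing}")
        shapes = {self.images[b].shape for b in Band}
        if len(shapes) != 1:
            raise ValueError(f"scene {self.scene_id}: band shapes differ: {shapes}")
        if self.true_homographies is not None:
            expected = set(MOVING_BANDS)
            if set(self.true_homographies) != expected:
                raise ValueError(
                    "true_homographies must cover exactly the four moving bands"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[REFERENCE_BAND].shape

    @property
    def reference_image(self) -> np.ndarray:
        return self.images[REFERENCE_BAND]


def ensure_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Normalize a mask raster to uint8 {0, 1}.

    Accepts boolean, {0,1} or {0,255} input; anything else is an error.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.dtype == bool:
        return mask.astype(np.uint8)
    vals = np.unique(mask)
    if np.isin(vals, (0, 1)).all():
        return mask.astype(np.uint8)
    if np.isin(vals, (0, 255)).all():
        return (mask > 0).astype(np.uint8)
    raise ValueError(f"mask values {vals[:6]}... are not binary (0/1 or 0/255)")


# ---------------------------------------------------------------------------
# VIA JSON
# ---------------------------------------------------------------------------

#: Default band-token pattern: a band name delimited by '_', '-', '.' or the
#: string edges, e.g. "s1_blue.tif", "scene-nir.png".
DEFAULT_BAND_PATTERN = (
    r"(?:^|[_\-.])(blue|green|red|nir|rededge)(?:[_\-.]|$)"
)


def infer_band(filename: str, pattern: str = DEFAULT_BAND_PATTERN) -> Band:
    """Resolve the spectral band from an image filename.

    Longest token wins so that ``rededge`` is never swallowed by ``red``.
    """
    tokens = re.findall(pattern, filename.lower())
    if not tokens:
        raise BandPatternError(
            f"cannot resolve a band token from filename {filename!r} "
            f"with pattern {pattern!r}"
        )
    return Band(max(tokens, key=len))


def read_via_json(
    path: str | Path,
    band_pattern: str = DEFAULT_BAND_PATTERN,
    image_shape: tuple[int, int] | None = None,
) -> tuple[AnnotationSet, dict]:
    """Read a VIA project export into an :class:`AnnotationSet`.

    The VIA dialect: a top-level object keyed per image file, each entry
    carrying a ``filename`` and a list (or dict) of ``regions`` whose
    ``shape_attributes`` hold ``all_points_x`` / ``all_points_y`` polygon
    vertex lists.  Non-polygon shapes are rejected.

    Returns the annotation set and a metadata dict mapping each band to its
    source filename (plus any ``image_shape`` recorded in the file).
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    meta: dict = {"filenames": {}, "path": str(path)}
    if "_image_shape" in doc:
        image_shape = tuple(doc.pop("_image_shape"))
    regions: dict[Band, list[PolygonRegion]] = {}
    for key, entry in doc.items():
        filename = entry.get("filename", key)
        band = infer_band(filename, band_pattern)
        raw_regions = entry.get("regions", [])
        if isinstance(raw_regions, dict):  # older VIA exports use dicts
            raw_regions = [raw_regions[k] for k in sorted(raw_regions)]
        band_regions: list[PolygonRegion] = []
        for i, reg in enumerate(raw_regions):
            shape_attr = reg.get("shape_attributes", {})
            if shape_attr.get("name", "polygon") not in ("polygon", "polyline"):
                raise ViaFormatError(
                    f"{filename} region {i}: unsupported shape "
                    f"{shape_attr.get('name')!r} (only polygons are accepted)"
                )
            if "all_points_x" not in shape_attr or "all_points_y" not in shape_attr:
                raise ViaFormatError(
                    f"{filename} region {i}: missing all_points_x/all_points_y"
                )
            instance_id = int(
                reg.get("region_attributes", {}).get("instance_id", i)
            )
            band_regions.append(
                PolygonRegion(
                    xs=shape_attr["all_points_x"],
                    ys=shape_attr["all_points_y"],
                    instance_id=instance_id,
                )
            )
        regions[band] = band_regions
        meta["filenames"][band] = filename

    if image_shape is None:
        # Fall back to the tightest raster containing every vertex.
        h = w = 1
        for regs in regions.values():
            for r in regs:
                h = max(h, int(np.ceil(r.ys.max())) + 1)
                w = max(w, int(np.ceil(r.xs.max())) + 1)
        image_shape = (h, w)
    return AnnotationSet(regions=regions, source_image_shape=image_shape), meta


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (10.4 -> 10, 10.6 -> 11, -0.5 -> -1)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def write_via_json(
    annotations: AnnotationSet,
    path: str | Path,
    filenames: dict[Band, str] | None = None,
) -> None:
    """Write an :class:`AnnotationSet` as a VIA-compatible project JSON.

    Coordinates are stored integer-rounded (half away from zero) and keys are
    emitted in a stable sorted order so files diff cleanly.
    """
    path = Path(path)
    if filenames is None:
        filenames = {b: f"scene_{b.value}.png" for b in annotations.bands()}
    doc: dict = {"_image_shape": list(annotations.source_image_shape)}
    for band in sorted(annotations.bands(), key=lambda b: b.value):
        fname = filenames[band]
        doc[fname] = {
            "filename": fname,
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": _round_half_away(r.xs).tolist(),
                        "all_points_y": _round_half_away(r.ys).tolist(),
                    },
                    "region_attributes": {"instance_id": r.instance_id},
                }
                for r in annotations[band]
            ],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Rasterization and masking
# ---------------------------------------------------------------------------

def _rasterize_one(region: PolygonRegion, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one polygon: pixel value 1 iff the pixel center lies inside
    or on the boundary of the polygon (even-odd rule with on-edge inclusion).
    """
    h, w = shape
    poly = region.to_shapely()
    if not poly.is_valid:  # e.g. self-intersecting jittered outlines
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0:
        return np.zeros(shape, dtype=np.uint8)
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(np.floor(minx)), 0)
    y0 = max(int(np.floor(miny)), 0)
    x1 = min(int(np.ceil(maxx)), w - 1)
    y1 = min(int(np.ceil(maxy)), h - 1)
    out = np.zeros(shape, dtype=np.uint8)
    if x1 < x0 or y1 < y0:
        return out
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    # intersects == "inside or on boundary" for point queries
    inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel())
    out[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(gy.shape)
    return out


def rasterize(
    regions: list[PolygonRegion], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize polygons to a semantic {0,1} mask; overlapping instances union.

    Degenerate (zero-area) polygons contribute nothing; if *all* polygons are
    degenerate an empty mask is returned with a warning rather than an error.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("raster shape must be positive")
    out = np.zeros(shape, dtype=np.uint8)
    any_fg = False
    for region in regions:
        m = _rasterize_one(region, shape)
        if m.any():
            any_fg = True
        np.logical_or(out, m, out=out)
    if regions and not any_fg:
        warnings.warn("all polygons rasterized to empty masks", stacklevel=2)
    return out.astype(np.uint8)


def rasterize_instances(
    regions: list[PolygonRegion], shape: tuple[int, int]
) -> dict[int, np.ndarray]:
    """Per-instance masks; their pixelwise union equals :func:`rasterize`."""
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("raster shape must be positive")
    return {r.instance_id: _rasterize_one(r, shape) for r in regions}


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep image intensities where mask == 1, zero elsewhere."""
    image = np.asarray(image)
    mask = ensure_binary_mask(mask)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    return np.where(mask == 1, image, np.zeros((), dtype=image.dtype))
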