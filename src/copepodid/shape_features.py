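"""Morphometric descriptors of a segmented copepod silhouette.

Eleven features describe one specimen: area, convex area,
eccentricity, major/minor axis length, perimeter, solidity, equivalent
diameter, extent, orientation, and the percentage of silhouette area
in the lower (posterior) part of the region of interest.

The lower-ROI percentage is the one non-standard descriptor: after the
silhouette is rotated upright and flipped so the bulkier prosome
(head/thorax) is at the top, the bottom 60% of the bounding-box height
is declared the "lower part" and the feature is

    100 * (true pixels in the lower part) / (all true pixels).

A copepod genus with a long slender urosome carries more of its mass
in that lower band than a compact-bodied genus of the same overall
size, which is what makes the feature discriminative where area and
axis lengths overlap.

Conventions fixed here (the underlying toolboxes differ on these):

* axis lengths are 4*sqrt(eigenvalue) of the normalised second
  central-moment matrix with the +1/12 unit-pixel variance correction;
* perimeter is the length of the 8-connected outer boundary polygon
  (Moore neighbour tracing; diagonal steps count sqrt(2));
* the convex hull is taken over pixel-corner coordinates and
  rasterised by pixel-centre inclusion;
* the ``orientation`` feature records the pre-rotation orientation
  (after rotation it is 90 degrees for every specimen and carries no
  information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.morphology import convex_hull_image

from .image_io import RasterImage, load_image
from .preprocess import FilterSpec, median_filter, order_statistic_edge
from .segmentation import (
    BinaryMask,
    SegmentationParams,
    extract_roi,
    measure_region,
    normalize_orientation,
    second_moment_axes,
    segment,
)

FEATURE_NAMES = (
    "area",
    "convex_area",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "solidity",
    "equivdiameter",
    "extent",
    "orientation",
    "lower_roi_pct",
)


@dataclass(frozen=True)
class LowerRoiParams:
    """Fraction of the ROI height counted as the lower (posterior) part."""

    ratio: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("ratio must lie in (0, 1)")


@dataclass(frozen=True)
class FeatureVector:
    area: float
    convex_area: float
    eccentricity: float
    major_axis_length: float
    minor_axis_length: float
    perimeter: float
    solidity: float
    equivdiameter: float
    extent: float
    orientation: float
    lower_roi_pct: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


_MOORE = (  # clockwise Moore neighbourhood, starting west
    (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
)


def boundary_trace(mask: BinaryMask) -> np.ndarray:
    """Outer boundary pixels of a connected region, in tracing order.

    Moore neighbour tracing with Jacob's stopping criterion (terminate
    on re-entering the start pixel from the same direction); a single
    isolated pixel yields a 1-point "boundary".
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no region")
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), bool)
    padded[1:-1, 1:-1] = mask
    start = (int(rows[0]) + 1, int(cols[0]) + 1)  # first in row-major scan
    boundary = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)  # west neighbour is background
    first_step: tuple | None = None
    while True:
        d0 = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        prev = backtrack
        for i in range(1, 9):
            dr, dc = _MOORE[(d0 + i) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel
            break
        step = (cur, nxt)
        if first_step is None:
            first_step = step
        elif step == first_step:
            break
        boundary.append(nxt)
        backtrack = prev
        cur = nxt
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.array(boundary) - 1


def perimeter_8connected(mask: BinaryMask) -> float:
    """Length of the closed 8-connected boundary polygon."""
    pts = boundary_trace(mask)
    if len(pts) < 2:
        return 0.0
    closed = np.vstack([pts, pts[:1]])
    steps = np.diff(closed, axis=0)
    return float(np.sqrt((steps**2).sum(axis=1)).sum())


def basic_descriptors(mask: BinaryMask, orientation: float | None = None) -> FeatureVector:
    """The ten standard shape descriptors of a single-component mask.

    ``orientation`` overrides the measured value (used to record the
    pre-rotation pose); ``lower_roi_pct`` is left unset.
    """
    info = measure_region(mask)  # raises "no region" on empty masks
    area = float(info.area)
    hull = convex_hull_image(mask, offset_coordinates=True)
    convex_area = float(hull.sum())
    major, minor = second_moment_axes(mask)
    ecc = math.sqrt(max(0.0, 1.0 - (minor / major) ** 2)) if major > 0 else 0.0
    _, _, bh, bw = info.bounding_box
    return FeatureVector(
        area=area,
        convex_area=convex_area,
        eccentricity=ecc,
        major_axis_length=major,
        minor_axis_length=minor,
        perimeter=perimeter_8connected(mask),
        solidity=area / convex_area,
        equivdiameter=math.sqrt(4.0 * area / math.pi),
        extent=area / (bh * bw),
        orientation=info.orientation_deg if orientation is None else orientation,
    )


def _halves_mass(mask: BinaryMask) -> tuple[int, int]:
    """True-pixel counts in the top and bottom halves of the tight bbox.

    For odd heights the middle row belongs to neither half.
    """
    rows = np.nonzero(mask)[0]
    rmin, rmax = rows.min(), rows.max()
    h = rmax - rmin + 1
    rel = rows - rmin
    top = int((rel < h // 2).sum())
    bottom = int((rel >= h - h // 2).sum())
    return top, bottom


def orient_anterior_up(mask: BinaryMask) -> BinaryMask:
    """Flip the mask upside down if its lower half carries more mass.

    The copepod prosome (head end) is bulkier than the urosome, so the
    heavier bounding-box half is taken to be anterior and moved to the
    top.  An exact tie means no flip.
    """
    top, bottom = _halves_mass(mask)
    if bottom > top:
        return np.flipud(mask)
    return mask.copy()


def lower_roi_pct(mask: BinaryMask, params: LowerRoiParams = LowerRoiParams()) -> float:
    """Percentage of silhouette pixels in the posterior band of the ROI.

    The band is the bottom ceil(ratio * H) rows of the tight bounding
    box (H its height), so the value is invariant to canvas padding.
    """
    rows = np.nonzero(mask)[0]
    if rows.size == 0:
        raise ValueError("no region")
    rmin, rmax = rows.min(), rows.max()
    h = int(rmax - rmin + 1)
    band_rows = math.ceil(params.ratio * h)
    cutoff = rmax - band_rows  # rows strictly greater are in the band
    q = int((rows > cutoff).sum())
    return 100.0 * q / rows.size


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the image -> feature-vector chain needs."""

    median_spec: FilterSpec = FilterSpec()
    edge_spec: FilterSpec = FilterSpec()
    seg_params: SegmentationParams = SegmentationParams()
    lower_roi: LowerRoiParams = LowerRoiParams()
    compensate_halo: bool = True

    def with_min_area(self, min_area: int) -> "PipelineConfig":
        return replace(self, seg_params=replace(self.seg_params, min_area=min_area))


def segment_image(
    img: RasterImage | str, config: PipelineConfig = PipelineConfig()
) -> tuple[RasterImage, BinaryMask]:
    """Grayscale -> median -> edge -> cleaned single-specimen mask."""
    if not isinstance(img, RasterImage):
        img = load_image(img)
    smooth = median_filter(img, config.median_spec)
    edge = order_statistic_edge(smooth, config.edge_spec)
    mask = segment(
        edge, config.seg_params, config.edge_spec, config.compensate_halo
    )
    return smooth, mask


def extract_features(
    img: RasterImage | str, config: PipelineConfig = PipelineConfig()
) -> FeatureVector:
    """Run the full chain on one image and return all 11 features.

    The recorded ``orientation`` is the pre-rotation pose of the
    specimen; all other descriptors are measured on the upright,
    tightly cropped, anterior-up silhouette.
    """
    try:
        smooth, mask = segment_image(img, config)
    except ValueError as err:
        if "no specimen" in str(err):
            raise ValueError("no specimen found") from err
        raise
    pre_orientation = measure_region(mask).orientation_deg
    rot_gray, rot_mask = normalize_orientation(smooth, mask)
    _, roi_mask = extract_roi(rot_gray, rot_mask)
    roi_mask = orient_anterior_up(roi_mask)
    fv = basic_descriptors(roi_mask, orientation=pre_orientation)
    return replace(fv, lower_roi_pct=lower_roi_pct(roi_mask, config.lower_roi))
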