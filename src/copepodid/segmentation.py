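"""Binary segmentation of a single specimen from an edge map.

The currency of this module is the *binary mask*: a 2-D boolean numpy
array on the same pixel grid as the source image.  The segmentation
chain turns the local-range edge map into a clean specimen silhouette:

    binarize (Otsu) -> clear_border -> fill_holes -> undo_edge_halo
    -> remove_small_objects -> keep_largest

then normalises the specimen's orientation to 90 degrees (major axis
vertical) and crops the tight region of interest.

``undo_edge_halo`` deserves a note.  A local-range edge detector with a
k x k window responds at every pixel whose window straddles the body
boundary, so the filled edge mask is exactly the true silhouette
dilated by the window's reflected support.  Eroding with the same
window (reflected anchoring) inverts that dilation exactly for convex
boundaries and reduces to a morphological closing otherwise, so the
recovered silhouette area is unbiased rather than inflated by half the
window size all around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image_io import RasterImage
from .preprocess import FilterSpec

logger = logging.getLogger(__name__)

#: Type alias: masks are plain 2-D boolean arrays.
BinaryMask = np.ndarray


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and size-filter settings.

    ``min_area`` defaults to 50000 px^2, which is coupled to the
    2448 x 1920 micrograph resolution it was chosen for; smaller frames
    need a proportionally smaller cutoff (scale by the area ratio).
    """

    min_area: int = 50000
    threshold_mode: str = "otsu"
    fixed_threshold: float | None = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_mode='fixed'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class RegionInfo:
    """Second-moment summary of a connected pixel region.

    ``orientation_deg`` is the angle in (-90, 90] between the x-axis
    and the major axis of the ellipse with the same second moments as
    the region, measured with the y-axis pointing *up* (so a region
    elongated along increasing row and column has negative
    orientation).  ``bounding_box`` is (min_row, min_col, height,
    width), 0-based and half-open.
    """

    area: int
    centroid: tuple[float, float]
    orientation_deg: float
    bounding_box: tuple[int, int, int, int]


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def binarize(edge_img: RasterImage, params: SegmentationParams = SegmentationParams()) -> BinaryMask:
    """Threshold an intensity image into a boolean mask (true = above).

    In ``otsu`` mode the threshold maximises the between-class variance
    over a 256-bin histogram of the image.
    """
    px = edge_img.pixels
    if params.threshold_mode == "fixed":
        thr = float(params.fixed_threshold)
    else:
        thr = otsu_threshold(px)
    return px > thr


def otsu_threshold(px: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the intensities."""
    if np.ptp(px) == 0:
        raise ValueError("degenerate histogram: image is constant")
    return float(threshold_otsu(px, nbins=256))


def clear_border(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Remove every component touching the image border."""
    labels, _ = ndi.label(mask, structure=_structure(connectivity))
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = border[border != 0]
    return mask & ~np.isin(labels, border)


def fill_holes(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Fill background regions not connected to the image border.

    The hole-background connectivity is complementary to the foreground
    connectivity (8-connected foreground implies 4-connected holes).
    """
    comp_structure = _structure(4 if connectivity == 8 else 8)
    return ndi.binary_fill_holes(mask, structure=comp_structure)


def remove_small_objects(
    mask: BinaryMask, min_area: int, connectivity: int = 8
) -> BinaryMask:
    """Drop components with pixel count strictly below ``min_area``."""
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


def undo_edge_halo(mask: BinaryMask, spec: FilterSpec = FilterSpec()) -> BinaryMask:
    """Erode away the half-window halo left by local-range edge detection.

    The erosion uses the reflected anchoring of the edge window so that
    (dilate by edge support) -> (this erosion) is the identity on
    convex silhouettes and a closing in general.
    """
    origin = tuple(-1 if k % 2 == 0 else 0 for k in spec.size)
    return ndi.minimum_filter(
        mask, size=spec.size, mode="constant", cval=False, origin=origin
    )


def keep_largest(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the largest component, warning if several survive."""
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    if n == 0:
        raise ValueError("no specimen found")
    if n > 1:
        logger.warning("%d components after size filtering; keeping largest", n)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def measure_region(mask: BinaryMask) -> RegionInfo:
    """Area, centroid, second-moment orientation and bounding box.

    The orientation is 0.5 * atan2(2*mu11, mu20 - mu02) in degrees,
    where mu_pq are per-pixel-normalised central moments of the pixel
    set in x = column, y = -row coordinates, with 1/12 added to mu20
    and mu02 (the variance of a unit square pixel) so a single pixel
    has a well-defined circular ellipse.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no region")
    r0, c0 = rows.mean(), cols.mean()
    x = cols - c0
    y = -(rows - r0)
    mu20 = np.mean(x * x) + 1.0 / 12.0
    mu02 = np.mean(y * y) + 1.0 / 12.0
    mu11 = np.mean(x * y)
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    deg = float(np.degrees(theta))
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    return RegionInfo(
        area=int(rows.size),
        centroid=(float(r0), float(c0)),
        orientation_deg=deg,
        bounding_box=(int(rmin), int(cmin), int(rmax - rmin + 1), int(cmax - cmin + 1)),
    )


def axial_difference_deg(a: float, b: float) -> float:
    """Smallest angle between two undirected axes (degrees, in [0, 90]).

    Orientations are axial quantities: 89.9 and -89.9 describe nearly
    the same major axis.
    """
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def second_moment_axes(mask: BinaryMask) -> tuple[float, float]:
    """(major, minor) axis lengths of the second-moment ellipse.

    Lengths are 4 * sqrt(eigenvalue) of the corrected normalised
    central-moment matrix, i.e. the axes of the ellipse with the same
    second moments as the pixel set.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no region")
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20 = np.mean(x * x) + 1.0 / 12.0
    mu02 = np.mean(y * y) + 1.0 / 12.0
    mu11 = np.mean(x * y)
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    lam1 = (mu20 + mu02) / 2.0 + common
    lam2 = (mu20 + mu02) / 2.0 - common
    return 4.0 * float(np.sqrt(lam1)), 4.0 * float(np.sqrt(max(lam2, 0.0)))


def normalize_orientation(
    gray: RasterImage, mask: BinaryMask
) -> tuple[RasterImage, BinaryMask]:
    """Rotate image and mask so the specimen's major axis is vertical.

    Rotation is by (90 deg - orientation) with canvas expansion;
    nearest-neighbour interpolation preserves mask binarity, bilinear
    is used for the grayscale.  Pixels rotated in from outside the
    canvas are 0 / false.
    """
    info = measure_region(mask)
    angle = 90.0 - info.orientation_deg
    if abs(angle) < 1e-9:
        return gray, mask.copy()
    rot_mask = ndi.rotate(mask, angle, reshape=True, order=0, mode="constant", cval=False)
    rot_gray = ndi.rotate(
        gray.pixels, angle, reshape=True, order=1, mode="constant", cval=0.0
    )
    return RasterImage(rot_gray, source_path=gray.source_path), rot_mask.astype(bool)


def extract_roi(gray: RasterImage, mask: BinaryMask) -> tuple[RasterImage, BinaryMask]:
    """Crop both grids to the mask's tight bounding box."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no specimen found")
    rs = slice(rows.min(), rows.max() + 1)
    cs = slice(cols.min(), cols.max() + 1)
    return RasterImage(gray.pixels[rs, cs], source_path=gray.source_path), mask[rs, cs]


def segment(
    edge_img: RasterImage,
    params: SegmentationParams = SegmentationParams(),
    edge_spec: FilterSpec = FilterSpec(),
    compensate_halo: bool = True,
) -> BinaryMask:
    """Full cleaning chain from edge map to single-specimen mask."""
    mask = binarize(edge_img, params)
    mask = clear_border(mask, params.connectivity)
    mask = fill_holes(mask, params.connectivity)
    if compensate_halo:
        mask = undo_edge_halo(mask, edge_spec)
    mask = remove_small_objects(mask, params.min_area, params.connectivity)
    return keep_largest(mask, params.connectivity)
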