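"""Nucleus segmentation and perinuclear/peripheral partitioning of the cytoplasm.

The intracellular space of a single cell is split into two regions: a
*perinuclear* band of fixed physical width (default 3 µm) measured outward
from the nucleus boundary, and a *peripheral* region covering the remainder
of the cell interior.  Distances are exact Euclidean distances computed on
the pixel raster and converted to physical units through the pixel size, so
the band is resolution independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _label, regionprops

#: default perinuclear band width, nm (3 µm band immediately outside the nucleus)
DEFAULT_BAND_WIDTH_NM = 3000.0

REGION_NUCLEUS = "nucleus"
REGION_PERINUCLEAR = "perinuclear"
REGION_PERIPHERAL = "peripheral"
REGION_OUTSIDE = "outside"


class SegmentationError(ValueError):
    """Raised when the nuclear channel does not contain exactly one nucleus."""


@dataclass(frozen=True)
class RegionMasks:
    """Boolean rasters partitioning one cell into nucleus / perinuclear / peripheral.

    Invariants (enforced at construction):

    * the three masks are pairwise disjoint;
    * perinuclear ∪ peripheral equals the cell interior minus the nucleus;
    * every perinuclear pixel lies within ``band_width`` nm of the nucleus
      boundary (closed upper bound: pixels at exactly ``band_width`` belong
      to the band).
    """

    nucleus_mask: np.ndarray
    perinuclear_mask: np.ndarray
    peripheral_mask: np.ndarray
    pixel_size: float  # nm / pixel
    band_width: float = DEFAULT_BAND_WIDTH_NM  # nm

    def __post_init__(self) -> None:
        for a, b in (
            (self.nucleus_mask, self.perinuclear_mask),
            (self.nucleus_mask, self.peripheral_mask),
            (self.perinuclear_mask, self.peripheral_mask),
        ):
            if np.any(a & b):
                raise ValueError("region masks must be pairwise disjoint")

    @property
    def cell_mask(self) -> np.ndarray:
        """Whole-cell mask (nucleus plus both cytoplasmic regions)."""
        return self.nucleus_mask | self.perinuclear_mask | self.peripheral_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.nucleus_mask.shape

    def areas_um2(self) -> dict[str, float]:
        """Region areas in µm²."""
        px_area = (self.pixel_size / 1000.0) ** 2
        return {
            REGION_NUCLEUS: float(self.nucleus_mask.sum() * px_area),
            REGION_PERINUCLEAR: float(self.perinuclear_mask.sum() * px_area),
            REGION_PERIPHERAL: float(self.peripheral_mask.sum() * px_area),
        }


def segment_nucleus(
    nucleus_image: np.ndarray,
    *,
    ambiguity_ratio: float = 0.5,
    min_area_px: int = 16,
) -> np.ndarray:
    """Segment the single dominant nucleus from a nuclear-stain image.

    Otsu threshold, hole filling and connected-component selection.  If no
    component survives, or a second component has area within
    ``ambiguity_ratio`` of the largest, the field is ambiguous and a
    :class:`SegmentationError` is raised — the caller must crop to one cell.

    Parameters
    ----------
    nucleus_image
        Single-channel 2-D image with one bright nuclear object.
    ambiguity_ratio
        Second-to-largest component areas with ratio above this value are
        treated as competing nuclei.
    min_area_px
        Components smaller than this are discarded as debris.

    Returns
    -------
    numpy.ndarray
        Boolean mask of the nucleus (one connected component, holes filled).
    """
    img = np.asarray(nucleus_image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.max() <= img.min():
        raise SegmentationError("no nuclear object found: image is constant")
    thresh = threshold_otsu(img)
    binary = ndimage.binary_fill_holes(img > thresh)
    labels = _label(binary)
    areas = sorted(
        (p.area, p.label) for p in regionprops(labels) if p.area >= min_area_px
    )
    if not areas:
        raise SegmentationError("no nuclear object found above the size floor")
    if len(areas) > 1 and areas[-2][0] >= ambiguity_ratio * areas[-1][0]:
        raise SegmentationError(
            f"ambiguous field: {len(areas)} comparable bright objects; "
            "crop to a single cell before segmentation"
        )
    return labels == areas[-1][1]


def build_region_masks(
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    band_width: float = DEFAULT_BAND_WIDTH_NM,
    pixel_size: float = 100.0,
) -> RegionMasks:
    """Partition the cell interior into the perinuclear band and the periphery.

    The perinuclear band is the set of cytoplasmic pixels whose Euclidean
    distance to the nucleus is positive and at most ``band_width`` nm;
    the peripheral region is every remaining cytoplasmic pixel.

    Parameters
    ----------
    nucleus_mask, cell_mask
        Boolean rasters; the nucleus must be strictly contained in the cell.
    band_width
        Physical band width in nm (> 0).
    pixel_size
        nm per pixel.

    Raises
    ------
    ValueError
        If the nucleus is not contained in the cell or ``band_width <= 0``.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if nucleus_mask.shape != cell_mask.shape:
        raise ValueError("nucleus and cell masks must share a shape")
    if band_width <= 0:
        raise ValueError(f"band_width must be positive, got {band_width}")
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    if np.any(nucleus_mask & ~cell_mask):
        raise ValueError("nucleus_mask must be contained in cell_mask")

    # distance (px) from each non-nucleus pixel to the nearest nucleus pixel
    dist_px = ndimage.distance_transform_edt(~nucleus_mask)
    dist_nm = dist_px * pixel_size
    cytoplasm = cell_mask & ~nucleus_mask
    perinuclear = cytoplasm & (dist_nm > 0) & (dist_nm <= band_width)
    peripheral = cytoplasm & ~perinuclear
    return RegionMasks(
        nucleus_mask=nucleus_mask,
        perinuclear_mask=perinuclear,
        peripheral_mask=peripheral,
        pixel_size=float(pixel_size),
        band_width=float(band_width),
    )


def assign_region(point: tuple[float, float], masks: RegionMasks) -> str:
    """Label the region containing a pixel coordinate ``(row, col)``.

    Fractional coordinates are resolved to the nearest pixel center.
    Out-of-bounds points are rejected.
    """
    r, c = int(round(point[0])), int(round(point[1]))
    h, w = masks.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"point {point} outside image bounds {masks.shape}")
    if masks.nucleus_mask[r, c]:
        return REGION_NUCLEUS
    if masks.perinuclear_mask[r, c]:
        return REGION_PERINUCLEAR
    if masks.peripheral_mask[r, c]:
        return REGION_PERIPHERAL
    return REGION_OUTSIDE
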