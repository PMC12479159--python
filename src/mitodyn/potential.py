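"""Regional mitochondrial inner-membrane potential from TMRM images.

TMRM accumulates in mitochondria in proportion to the inner-membrane
potential, so the readout is the *background-subtracted* mean mitochondrial
pixel intensity per intracellular region.  Each detected mitochondrion is
one measurement: its mean intensity is paired with a local background ring
sampled 2–4 px beyond its outline (excluding other mitochondria), so local
illumination is cancelled.  Raw regional values are then normalized to the
perinuclear mean of the control condition, making the control perinuclear
value 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dynamics import DetectionParams, detect_mitochondria
from .regions import REGION_PERINUCLEAR, REGION_PERIPHERAL, RegionMasks, assign_region

#: minimum number of per-mitochondrion measurements required per region
MIN_MEASUREMENTS_PER_REGION = 12


@dataclass(frozen=True)
class RegionalPotential:
    """Background-subtracted TMRM intensity per region for one cell.

    ``raw_*`` values are mean mitochondrial intensity minus mean local
    background (clamped at zero: the potential proxy cannot be negative;
    ``n_clamped`` counts affected measurements).  ``normalized_*`` fields are
    filled by :func:`normalize_potential`.
    """

    raw_perinuclear: float
    raw_peripheral: float
    n_perinuclear: int
    n_peripheral: int
    n_clamped: int = 0
    normalized_perinuclear: float | None = None
    normalized_peripheral: float | None = None


def _component_labels(mito_mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mito_mask)
    if mask.dtype == bool:
        labels, _ = ndimage.label(mask)
        return labels
    return mask.astype(int)


def measure_potential(
    tmrm_image: np.ndarray,
    masks: RegionMasks,
    mito_mask: np.ndarray | None = None,
    *,
    min_measurements: int = MIN_MEASUREMENTS_PER_REGION,
    detection_params: DetectionParams = DetectionParams(),
    ring_inner_px: int = 2,
    ring_outer_px: int = 4,
) -> RegionalPotential:
    """Measure raw regional potential from one TMRM image.

    Parameters
    ----------
    tmrm_image
        Single-frame TMRM channel matching ``masks``.
    masks
        Region partition from the paired nucleus image.
    mito_mask
        Boolean or labeled raster of mitochondrial pixels.  When omitted the
        mitochondria are detected from the TMRM image itself with the
        standard detector.
    min_measurements
        Minimum mitochondria sampled per region; fewer is rejected naming
        the deficient region.
    ring_inner_px, ring_outer_px
        The local background ring spans dilations ``inner``–``outer`` px
        beyond each mitochondrion, excluding all mitochondrial pixels.
    """
    img = np.asarray(tmrm_image, dtype=float)
    if img.shape != masks.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {masks.shape}")
    if mito_mask is None:
        dets = detect_mitochondria(img, masks, detection_params)
        mask = np.zeros(img.shape, dtype=bool)
        # rebuild the footprint from the detector's threshold step
        from skimage.filters import gaussian, threshold_otsu

        signal = img - gaussian(img, sigma=detection_params.bg_sigma_px,
                                preserve_range=True)
        if dets and signal.max() > signal.min():
            mask = signal > threshold_otsu(signal)
        labels = _component_labels(mask)
    else:
        labels = _component_labels(mito_mask)

    all_mito = labels > 0
    all_mito_dilated = ndimage.binary_dilation(all_mito, iterations=1)
    n_comp = labels.max()
    samples: dict[str, list[tuple[float, float]]] = {
        REGION_PERINUCLEAR: [],
        REGION_PERIPHERAL: [],
    }
    objects = ndimage.find_objects(labels)
    for lab in range(1, n_comp + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        pad = ring_outer_px + 1
        rs = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, img.shape[0]))
        cs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, img.shape[1]))
        comp = labels[rs, cs] == lab
        rr, cc = np.nonzero(comp)
        r0 = rr.mean() + rs.start
        c0 = cc.mean() + cs.start
        region = assign_region((r0, c0), masks)
        if region not in samples:
            continue
        ring = ndimage.binary_dilation(comp, iterations=ring_outer_px) & ~(
            ndimage.binary_dilation(comp, iterations=ring_inner_px)
        )
        ring &= ~all_mito_dilated[rs, cs]
        if not ring.any():
            continue
        mito_mean = float(img[rs, cs][comp].mean())
        bg_mean = float(img[rs, cs][ring].mean())
        samples[region].append((mito_mean, bg_mean))

    for region, vals in samples.items():
        if len(vals) < min_measurements:
            raise ValueError(
                f"only {len(vals)} mitochondrial measurements in the {region} "
                f"region; need at least {min_measurements}"
            )

    n_clamped = 0
    raw: dict[str, float] = {}
    for region, vals in samples.items():
        arr = np.asarray(vals)
        value = float(arr[:, 0].mean() - arr[:, 1].mean())
        if value < 0:
            n_clamped += 1
            value = 0.0
        raw[region] = value
    return RegionalPotential(
        raw_perinuclear=raw[REGION_PERINUCLEAR],
        raw_peripheral=raw[REGION_PERIPHERAL],
        n_perinuclear=len(samples[REGION_PERINUCLEAR]),
        n_peripheral=len(samples[REGION_PERIPHERAL]),
        n_clamped=n_clamped,
    )


def control_reference(measurements: Sequence[RegionalPotential]) -> float:
    """Mean raw perinuclear value of the control group (the normalizer)."""
    if not measurements:
        raise ValueError("no control measurements supplied")
    return float(np.mean([m.raw_perinuclear for m in measurements]))


def normalize_potential(
    measurements: Sequence[RegionalPotential], reference: float
) -> list[RegionalPotential]:
    """Divide every raw regional value by the control perinuclear reference.

    By construction the mean normalized perinuclear value of the control
    group itself equals 1.
    """
    if reference <= 0:
        raise ValueError(f"control reference must be positive, got {reference}")
    return [
        replace(
            m,
            normalized_perinuclear=m.raw_perinuclear / reference,
            normalized_peripheral=m.raw_peripheral / reference,
        )
        for m in measurements
    ]
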