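"""Mitochondrial detection, tracking, motility statistics and regional volumes.

Mitochondria are detected per frame by background subtraction and Otsu
thresholding, linked across frames by greedy mutual-nearest-neighbor
matching with a distance gate, and summarised by their *net displacement*:
the Euclidean distance between a track's first- and last-frame centroids
over the acquisition epoch.  Net displacements follow a log-normal
distribution, so their central tendency is the geometric mean and their
spread the (multiplicative) geometric standard deviation.

Coordinates: image rasters are indexed ``[row, col]``; physical positions
are ``(x, y)`` in nm with ``x = col * pixel_size`` and ``y = row *
pixel_size``.  Displacements are reported in nm and volumes in µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as _label, regionprops

from .regions import REGION_PERINUCLEAR, REGION_PERIPHERAL, RegionMasks, assign_region

#: displacement floor applied before log transforms, nm (half the nominal
#: localization precision; a log-normal fit needs positive support)
DISPLACEMENT_FLOOR_NM = 1.0


@dataclass(frozen=True)
class MitoDetection:
    """One mitochondrion in one frame: centroid and rod dimensions in nm."""

    frame_index: int
    x_nm: float
    y_nm: float
    length_nm: float
    width_nm: float
    region: str | None = None

    def __post_init__(self) -> None:
        if not (self.length_nm >= self.width_nm > 0):
            raise ValueError(
                f"need length >= width > 0, got ({self.length_nm}, {self.width_nm})"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x_nm, self.y_nm)


@dataclass
class TrackSet:
    """Per-mitochondrion trajectories over an acquisition epoch."""

    tracks: list[list[MitoDetection]]
    frame_interval: float  # s
    n_frames: int

    def __post_init__(self) -> None:
        for t in self.tracks:
            idx = [d.frame_index for d in t]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("frame indices within a track must strictly increase")

    @property
    def epoch_s(self) -> float:
        """Duration of the acquisition epoch in seconds."""
        return (self.n_frames - 1) * self.frame_interval

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class MotilityDistribution:
    """Log-normal summary of net displacements for one region/condition."""

    displacements: np.ndarray  # nm
    geometric_mean: float  # nm
    geometric_sd: float  # dimensionless, >= 1
    region: str | None
    n: int

    def log_density(self, grid_nm: np.ndarray) -> np.ndarray:
        """Fitted log-normal pdf evaluated on ``grid_nm`` (for log-axis plots)."""
        mu, sigma = math.log(self.geometric_mean), math.log(self.geometric_sd)
        g = np.asarray(grid_nm, dtype=float)
        if sigma == 0:
            return np.where(g == self.geometric_mean, np.inf, 0.0)
        return (
            1.0
            / (g * sigma * math.sqrt(2 * math.pi))
            * np.exp(-((np.log(g) - mu) ** 2) / (2 * sigma**2))
        )


@dataclass(frozen=True)
class RegionalVolume:
    """Total mitochondrial volume per intracellular region, µm³."""

    v_perinuclear: float
    v_peripheral: float

    @property
    def fraction_perinuclear(self) -> float:
        total = self.v_perinuclear + self.v_peripheral
        if total <= 0:
            raise ValueError("total mitochondrial volume must be positive")
        return self.v_perinuclear / total


@dataclass(frozen=True)
class DetectionParams:
    """Per-frame detection settings.

    ``bg_sigma_px`` sets the Gaussian background estimate that is subtracted
    before thresholding; ``min_area_px`` discards sub-resolution debris.
    """

    min_area_px: int = 4
    bg_sigma_px: float = 12.0
    threshold_method: str = "otsu"


def detect_mitochondria(
    frame: np.ndarray,
    masks: RegionMasks,
    params: DetectionParams = DetectionParams(),
) -> list[MitoDetection]:
    """Detect mitochondria in one frame.

    Background (large-sigma Gaussian of the frame) is subtracted, the result
    thresholded (Otsu), and connected components at least ``min_area_px``
    pixels in size are kept.  Each component yields an intensity-weighted
    centroid (sub-pixel), and length/width from the extent of the component
    along its principal axes.  The region label comes from the centroid's
    position in ``masks``; an empty frame returns an empty list.
    """
    img = np.asarray(frame, dtype=float)
    if img.shape != masks.shape:
        raise ValueError(f"frame shape {img.shape} != mask shape {masks.shape}")
    if params.threshold_method != "otsu":
        raise ValueError(f"unknown threshold_method {params.threshold_method!r}")
    px = masks.pixel_size

    signal = img - gaussian(img, sigma=params.bg_sigma_px, preserve_range=True)
    finite = signal[np.isfinite(signal)]
    if finite.size == 0 or finite.max() <= finite.min():
        return []
    # Otsu with a robust noise floor: when few bright objects are present the
    # Otsu split can fall inside the noise distribution, so the threshold is
    # never taken below 5 scaled MADs above the background median
    med = float(np.median(signal))
    mad = float(np.median(np.abs(signal - med)))
    noise_floor = med + 5.0 * 1.4826 * mad
    thr = max(threshold_otsu(signal), noise_floor)
    binary = signal > thr
    if not binary.any():
        return []
    labels = _label(binary)
    weights = np.clip(signal, 0, None)

    out: list[MitoDetection] = []
    pad = 3
    for prop in regionprops(labels):
        if prop.area < params.min_area_px:
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        w = weights[rr, cc]
        if w.sum() <= 0:
            continue
        # centroid over the component dilated past the threshold contour:
        # the smooth intensity tails then carry the sub-pixel information and
        # frame-to-frame flicker of the Otsu boundary does not move it
        r_lo, c_lo, r_hi, c_hi = prop.bbox
        rs = slice(max(r_lo - pad, 0), min(r_hi + pad, labels.shape[0]))
        cs = slice(max(c_lo - pad, 0), min(c_hi + pad, labels.shape[1]))
        local = labels[rs, cs]
        dil = ndimage.binary_dilation(local == prop.label, iterations=2)
        dil &= (local == prop.label) | (local == 0)
        drr, dcc = np.nonzero(dil)
        dw = weights[rs, cs][drr, dcc]
        r0 = float(np.average(drr, weights=dw)) + rs.start
        c0 = float(np.average(dcc, weights=dw)) + cs.start
        # dimensions from the half-maximum contour: under symmetric blur the
        # half-max of an edge sits on the true boundary, so extents measured
        # there track the physical rod rather than the threshold level
        half_max = 0.5 * np.percentile(w, 95)
        core = w >= half_max
        if core.sum() >= 2:
            length_px, width_px = _principal_extents(rr[core] - r0, cc[core] - c0)
        else:
            length_px, width_px = _principal_extents(rr - r0, cc - c0)
        region = assign_region((r0, c0), masks)
        try:
            det = MitoDetection(
                frame_index=0,
                x_nm=c0 * px,
                y_nm=r0 * px,
                length_nm=max(length_px, 1.0) * px,
                width_nm=max(width_px, 1.0) * px,
                region=region,
            )
        except ValueError:
            # width can exceed length by a fraction of a pixel on tiny blobs
            side = max(length_px, width_px, 1.0) * px
            det = MitoDetection(0, c0 * px, r0 * px, side, side, region)
        out.append(det)
    return out


def _principal_extents(dr: np.ndarray, dc: np.ndarray) -> tuple[float, float]:
    """Extent (px) of a pixel cloud along its principal axes, longest first."""
    coords = np.stack([dr, dc], axis=1).astype(float)
    if len(coords) == 1:
        return 1.0, 1.0
    cov = np.cov(coords.T)
    _, vecs = np.linalg.eigh(np.atleast_2d(cov))
    proj = coords @ vecs
    # +0.5: the bounding contour passes between the outermost included pixel
    # centers and their excluded neighbors
    spans = proj.max(axis=0) - proj.min(axis=0) + 0.5
    lo, hi = float(spans.min()), float(spans.max())
    return hi, lo


def _with_frame(det: MitoDetection, frame_index: int) -> MitoDetection:
    return MitoDetection(
        frame_index, det.x_nm, det.y_nm, det.length_nm, det.width_nm, det.region
    )


def link_tracks(
    detections: Iterable[MitoDetection] | Sequence[Sequence[MitoDetection]],
    max_disp: float,
    *,
    frame_interval: float = 3.0,
    n_frames: int | None = None,
    max_gap: int = 2,
) -> TrackSet:
    """Link per-frame detections into tracks.

    Greedy mutual-nearest-neighbor matching between each frame's detections
    and the open tracks: a pair is linked only when each is the other's
    nearest candidate and their separation is at most ``max_disp`` nm.
    Unmatched detections start new tracks; a track left unmatched for more
    than ``max_gap`` frames is closed.  Links that bridge a gap are filled by
    linear interpolation of the missing frames.
    """
    # group by frame
    if detections and isinstance(next(iter(detections)), MitoDetection):
        flat = list(detections)  # type: ignore[arg-type]
    else:
        flat = [d for fr in detections for d in fr]  # type: ignore[union-attr]
    by_frame: dict[int, list[MitoDetection]] = {}
    for d in flat:
        by_frame.setdefault(d.frame_index, []).append(d)
    frames = sorted(by_frame)
    if n_frames is None:
        n_frames = (frames[-1] + 1) if frames else 0

    open_tracks: list[list[MitoDetection]] = []
    closed: list[list[MitoDetection]] = []
    for f in frames:
        dets = by_frame[f]
        # retire tracks whose last detection is too old to bridge
        still_open = []
        for t in open_tracks:
            if f - t[-1].frame_index > max_gap + 1:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open

        matched_t: set[int] = set()
        matched_d: set[int] = set()
        if open_tracks and dets:
            tp = np.array([[t[-1].x_nm, t[-1].y_nm] for t in open_tracks])
            dp = np.array([[d.x_nm, d.y_nm] for d in dets])
            dist = np.linalg.norm(tp[:, None, :] - dp[None, :, :], axis=2)
            dist[dist > max_disp] = np.inf
            while True:
                work = dist.copy()
                work[list(matched_t), :] = np.inf
                work[:, list(matched_d)] = np.inf
                if not np.isfinite(work).any():
                    break
                # mutual nearest neighbors this round
                nn_d = work.argmin(axis=1)
                nn_t = work.argmin(axis=0)
                linked_any = False
                for ti in range(len(open_tracks)):
                    if ti in matched_t or not np.isfinite(work[ti, nn_d[ti]]):
                        continue
                    di = nn_d[ti]
                    if di in matched_d or nn_t[di] != ti:
                        continue
                    track = open_tracks[ti]
                    gap = f - track[-1].frame_index
                    if gap > 1:
                        track.extend(_interpolate(track[-1], dets[di], f))
                    track.append(_with_frame(dets[di], f))
                    matched_t.add(ti)
                    matched_d.add(di)
                    linked_any = True
                if not linked_any:
                    break
        for di, d in enumerate(dets):
            if di not in matched_d:
                open_tracks.append([_with_frame(d, f)])
    closed.extend(open_tracks)
    return TrackSet(tracks=closed, frame_interval=frame_interval, n_frames=n_frames)


def _interpolate(
    last: MitoDetection, nxt: MitoDetection, frame: int
) -> list[MitoDetection]:
    """Linearly interpolate detections across a bridged gap (exclusive ends)."""
    out = []
    span = frame - last.frame_index
    for k in range(1, span):
        a = k / span
        out.append(
            MitoDetection(
                last.frame_index + k,
                (1 - a) * last.x_nm + a * nxt.x_nm,
                (1 - a) * last.y_nm + a * nxt.y_nm,
                (1 - a) * last.length_nm + a * nxt.length_nm,
                (1 - a) * last.width_nm + a * nxt.width_nm,
                last.region,
            )
        )
    return out


def net_displacement(track: Sequence[MitoDetection]) -> float:
    """Euclidean distance (nm) between a track's first and last centroids."""
    if len(track) < 2:
        raise ValueError("net displacement needs a track spanning >= 2 frames")
    first, last = track[0], track[-1]
    return math.hypot(last.x_nm - first.x_nm, last.y_nm - first.y_nm)


def track_net_displacements(
    trackset: TrackSet,
    *,
    min_span: int | None = None,
    floor_nm: float = DISPLACEMENT_FLOOR_NM,
) -> tuple[np.ndarray, list[str | None], int]:
    """Net displacements (floored, nm) and first-frame region labels per track.

    Tracks spanning fewer than ``min_span`` frames (default: 2) are excluded;
    the excluded count is returned so callers can log it.  Region membership
    is fixed at the first-frame centroid even if the mitochondrion crosses
    the band during the epoch.
    """
    if min_span is None:
        min_span = 2
    disps: list[float] = []
    regions: list[str | None] = []
    excluded = 0
    for t in trackset.tracks:
        if len(t) < min_span:
            excluded += 1
            continue
        disps.append(max(net_displacement(t), floor_nm))
        regions.append(t[0].region)
    return np.asarray(disps), regions, excluded


def fit_lognormal(
    displacements: Sequence[float] | np.ndarray, region: str | None = None
) -> MotilityDistribution:
    """Fit the log-normal motility summary to a sample of net displacements.

    ``geometric_mean = exp(mean(log d))`` and ``geometric_sd = exp(sd(log d))``
    (sample sd, ddof=1).  Requires at least 3 strictly positive values.
    """
    d = np.asarray(displacements, dtype=float)
    if d.size < 3:
        raise ValueError(f"log-normal fit needs n >= 3 displacements, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("displacements must be positive (apply the floor first)")
    logs = np.log(d)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if d.size > 1 else 1.0
    return MotilityDistribution(
        displacements=d, geometric_mean=gm, geometric_sd=gsd, region=region, n=d.size
    )


def mito_volume(
    length_nm: float, width_nm: float, model: str = "spherocylinder"
) -> float:
    """Volume (µm³) of a rod with the given length and width.

    The default model is a spherocylinder of radius ``r = width/2``:
    ``V = π r² (L − W) + (4/3) π r³`` (a sphere when ``L == W``).  The
    ``"cylinder"`` alternative (``π r² L``) is exposed for sensitivity
    analysis of the regional volume fractions.
    """
    if width_nm <= 0:
        raise ValueError(f"width must be positive, got {width_nm}")
    if length_nm < width_nm:
        raise ValueError(f"need length >= width, got ({length_nm}, {width_nm})")
    length, width = length_nm / 1000.0, width_nm / 1000.0  # µm
    r = width / 2.0
    if model == "spherocylinder":
        return math.pi * r**2 * (length - width) + (4.0 / 3.0) * math.pi * r**3
    if model == "cylinder":
        return math.pi * r**2 * length
    raise ValueError(f"unknown volume model {model!r}")


def detection_volume(det: MitoDetection, model: str = "spherocylinder") -> float:
    return mito_volume(det.length_nm, det.width_nm, model)


def regional_volumes(
    detections: Sequence[MitoDetection],
    model: str = "spherocylinder",
    reference_frame: int | None = None,
    max_width_nm: float | None = None,
) -> RegionalVolume:
    """Sum per-mitochondrion volumes by region on a single reference frame.

    ``reference_frame`` defaults to the earliest frame present.  Detections
    must carry region labels; nucleus/outside labels are ignored.
    ``max_width_nm`` is a quality filter: components wider than any plausible
    single mitochondrion are unresolved clusters of touching organelles whose
    bounding-box volume is grossly inflated, and are excluded from the sums.
    """
    if not detections:
        raise ValueError("no detections to compute regional volumes from")
    if reference_frame is None:
        reference_frame = min(d.frame_index for d in detections)
    v = {REGION_PERINUCLEAR: 0.0, REGION_PERIPHERAL: 0.0}
    counted = 0
    for d in detections:
        if d.frame_index != reference_frame or d.region not in v:
            continue
        if max_width_nm is not None and d.width_nm > max_width_nm:
            continue
        v[d.region] += detection_volume(d, model)
        counted += 1
    if counted == 0:
        raise ValueError(
            f"no labeled detections on reference frame {reference_frame}"
        )
    return RegionalVolume(
        v_perinuclear=v[REGION_PERINUCLEAR], v_peripheral=v[REGION_PERIPHERAL]
    )


def track_regional_volumes(
    trackset: TrackSet, model: str = "spherocylinder"
) -> RegionalVolume:
    """Regional volumes from tracks, averaging dimensions over each track's frames.

    Dimension averaging suppresses per-frame measurement noise; the region
    label is the track's first-frame label.
    """
    v = {REGION_PERINUCLEAR: 0.0, REGION_PERIPHERAL: 0.0}
    counted = 0
    for t in trackset.tracks:
        region = t[0].region
        if region not in v:
            continue
        length = float(np.mean([d.length_nm for d in t]))
        width = float(np.mean([d.width_nm for d in t]))
        v[region] += mito_volume(max(length, width), min(length, width), model)
        counted += 1
    if counted == 0:
        raise ValueError("no labeled tracks to compute regional volumes from")
    return RegionalVolume(
        v_perinuclear=v[REGION_PERINUCLEAR], v_peripheral=v[REGION_PERIPHERAL]
    )


@dataclass
class StackAnalysis:
    """End-to-end result for one time-lapse stack."""

    trackset: TrackSet
    overall: MotilityDistribution
    by_region: dict[str, MotilityDistribution]
    volumes: RegionalVolume
    n_excluded_tracks: int = 0
    detection_params: DetectionParams = field(default_factory=DetectionParams)


def analyze_stack(
    stack: np.ndarray,
    masks: RegionMasks,
    *,
    frame_interval: float = 3.0,
    max_disp: float = 300.0,
    params: DetectionParams = DetectionParams(),
    min_track_span: int | None = None,
    max_width_nm: float | None = 900.0,
) -> StackAnalysis:
    """Detect, link and summarise a full time-lapse stack.

    The linking gate ``max_disp`` should sit well above the per-frame motion
    but below typical inter-mitochondrion spacing; a tight gate rejects the
    centroid jumps produced when touching mitochondria merge and split, and
    the resulting fragments are removed by the span filter.
    ``min_track_span`` defaults to ``n_frames - 4`` so that net displacements
    refer to (nearly) the whole acquisition epoch rather than fragments.
    ``max_width_nm`` excludes unresolved clusters from the volume sums (see
    :func:`regional_volumes`).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a (frames, H, W) stack, got {stack.shape}")
    n_frames = stack.shape[0]
    per_frame: list[list[MitoDetection]] = []
    for f in range(n_frames):
        dets = [
            _with_frame(d, f) for d in detect_mitochondria(stack[f], masks, params)
        ]
        per_frame.append(dets)
    ts = link_tracks(
        per_frame, max_disp, frame_interval=frame_interval, n_frames=n_frames
    )
    if min_track_span is None:
        min_track_span = max(2, n_frames - 4)
    disps, regions, excluded = track_net_displacements(ts, min_span=min_track_span)
    overall = fit_lognormal(disps)
    by_region = {}
    for reg in (REGION_PERINUCLEAR, REGION_PERIPHERAL):
        sel = np.array([r == reg for r in regions], dtype=bool)
        if sel.sum() >= 3:
            by_region[reg] = fit_lognormal(disps[sel], region=reg)
    # volumes from a single reference frame: every object is counted exactly
    # once regardless of how its track fragments later in the epoch
    volumes = regional_volumes(per_frame[0], max_width_nm=max_width_nm)
    return StackAnalysis(
        trackset=ts,
        overall=overall,
        by_region=by_region,
        volumes=volumes,
        n_excluded_tracks=excluded,
        detection_params=params,
    )
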