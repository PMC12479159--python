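"""Synthetic microscopy and respirometry data with exact ground truth.

This module generates the inputs the analysis pipeline consumes — two-channel
fluorescence time-lapse stacks (mitochondria + nucleus), single-frame TMRM /
nucleus image pairs, and plate-format OCR traces — together with the exact
quantities the pipeline is supposed to recover.  Cells are modeled as 2-D
disks with disk nuclei: the regional analysis depends only on masks, so the
simplified geometry isolates algorithm behavior from cell morphology.

Motility model: each mitochondrion's net displacement over the epoch is
drawn from a log-normal distribution (median ``geo_mean_displacement``,
multiplicative spread ``geo_sd``) and *imposed exactly* at the track level:
per-frame positions follow a Brownian bridge between the start point and an
endpoint placed at exactly the drawn distance, so the ground-truth net
displacement is sharp rather than emergent from a diffusion constant.

All randomness flows from a single integer seed through named substreams
(`numpy` ``SeedSequence`` spawn keys), so every artifact is reproducible
independently of generation order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

from .dynamics import MitoDetection, TrackSet
from .regions import RegionMasks, assign_region, build_region_masks
from .respirometry import MIN_BACKGROUND_WELLS, STAGES, PlateOCR


def substream(seed: int, *names: str) -> np.random.Generator:
    """Independent generator for a named substream of a master seed."""
    key = tuple(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# cell geometry and tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of one synthetic cell and its motility ground truth.

    Geometry is physical (nm) and converted to the raster through
    ``pixel_size``.  Defaults emulate the acquisition this pipeline targets:
    a 40x wide-field system (162.5 nm pixels), a 5-min epoch of 101 frames
    every 3 s, and sub-resolution mitochondrial motion (tens of nm net
    displacement per epoch).
    """

    image_shape: tuple[int, int] = (768, 768)  # (rows, cols) px
    pixel_size: float = 162.5  # nm / px
    nucleus_center: tuple[float, float] | None = None  # (row, col) px
    nucleus_radius: float = 8_000.0  # nm
    cell_radius: float = 30_000.0  # nm
    n_mito: int = 200
    mito_length_range: tuple[float, float] = (800.0, 2_200.0)  # nm
    mito_width_range: tuple[float, float] = (400.0, 600.0)  # nm
    perinuclear_fraction: float = 0.3
    geo_mean_displacement: float = 80.0  # nm, log-normal median
    geo_mean_peripheral: float | None = None  # nm; defaults to the same median
    geo_sd: float = 1.5  # multiplicative spread, >= 1
    n_frames: int = 101
    frame_interval: float = 3.0  # s
    band_width: float = 3_000.0  # nm, perinuclear band
    step_noise_nm: float = 30.0  # Brownian-bridge wiggle per frame step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError(
                f"nucleus_radius ({self.nucleus_radius}) must be smaller than "
                f"cell_radius ({self.cell_radius})"
            )
        h, w = self.image_shape
        rc = self.center_px
        margin_px = self.cell_radius / self.pixel_size
        if not (
            margin_px <= rc[0] <= h - 1 - margin_px
            and margin_px <= rc[1] <= w - 1 - margin_px
        ):
            raise ValueError(
                f"cell of radius {self.cell_radius} nm at center {rc} px does not "
                f"fit inside image {self.image_shape} at {self.pixel_size} nm/px"
            )
        if self.geo_sd < 1:
            raise ValueError(f"geo_sd must be >= 1, got {self.geo_sd}")
        if self.geo_mean_displacement <= 0:
            raise ValueError("geo_mean_displacement must be positive")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0 <= self.perinuclear_fraction <= 1:
            raise ValueError("perinuclear_fraction must be in [0, 1]")

    @property
    def center_px(self) -> tuple[float, float]:
        if self.nucleus_center is not None:
            return self.nucleus_center
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)

    @property
    def center_nm(self) -> tuple[float, float]:
        """Cell center as (x, y) nm."""
        r, c = self.center_px
        return (c * self.pixel_size, r * self.pixel_size)

    @property
    def epoch_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class CellGeometry:
    """Rasterized geometry of one synthetic cell plus its region masks."""

    spec: SyntheticCellSpec
    nucleus_image: np.ndarray
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    masks: RegionMasks


@dataclass
class GroundTruth:
    """Exact per-mitochondrion truth for one simulated cell.

    ``tracks`` has shape (n_mito, n_frames, 2) with (x, y) in nm; the net
    displacement of mitochondrion *i* equals the Euclidean distance between
    ``tracks[i, 0]`` and ``tracks[i, -1]`` exactly.
    """

    tracks: np.ndarray
    net_displacements: np.ndarray  # nm
    region_labels: list[str]
    dimensions: np.ndarray  # (n_mito, 2) length/width nm
    orientations: np.ndarray  # rad
    potential: dict[str, float] | None = None
    resp: dict[str, float] | None = None


def generate_cell(spec: SyntheticCellSpec) -> CellGeometry:
    """Rasterize the cell: nucleus channel image, cell mask, region masks."""
    h, w = spec.image_shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    r0, c0 = spec.center_px
    dist_nm = np.hypot(rr - r0, cc - c0) * spec.pixel_size
    nucleus_mask = dist_nm <= spec.nucleus_radius
    cell_mask = dist_nm <= spec.cell_radius

    rng = substream(spec.seed, "nucleus-image")
    img = np.where(nucleus_mask, 1.0, 0.05)
    img = img + rng.normal(0.0, 0.01, size=img.shape)
    masks = build_region_masks(
        nucleus_mask, cell_mask, band_width=spec.band_width, pixel_size=spec.pixel_size
    )
    return CellGeometry(
        spec=spec,
        nucleus_image=img.astype(np.float32),
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        masks=masks,
    )


def _sample_positions(
    spec: SyntheticCellSpec, rng: np.random.Generator, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions (nm) honoring the perinuclear seeding fraction.

    Returns positions (n, 2) and a boolean array marking perinuclear seeds.
    Radii are sampled area-uniformly within each annulus; a margin keeps rods
    clear of the cell edge.
    """
    if n is None:
        n = spec.n_mito
    margin = spec.mito_length_range[1] / 2.0
    n_peri = int(round(n * spec.perinuclear_fraction))
    band_outer = min(spec.nucleus_radius + spec.band_width, spec.cell_radius - margin)
    peri_out = n_peri > 0
    if peri_out and band_outer <= spec.nucleus_radius:
        raise ValueError("perinuclear band does not fit between nucleus and cell edge")
    if n - n_peri > 0 and band_outer >= spec.cell_radius - margin:
        raise ValueError("no peripheral room outside the band for peripheral seeds")
    is_peri = np.zeros(n, dtype=bool)
    is_peri[:n_peri] = True
    # one-pixel standoff from region boundaries so raster labels are sharp
    standoff = spec.pixel_size
    lo = np.where(is_peri, spec.nucleus_radius + standoff, band_outer + standoff)
    hi = np.where(is_peri, band_outer - standoff, spec.cell_radius - margin)
    cx, cy = spec.center_nm
    # dart throwing with a soft minimum separation: mitochondria are solid
    # bodies, so seeds repel at roughly one median rod length
    min_sep = float(np.mean(spec.mito_length_range)) * 0.8
    pos = np.empty((n, 2))
    for i in range(n):
        best_cand, best_d = None, -np.inf
        for _ in range(50):
            u = rng.uniform()
            r = np.sqrt(lo[i] ** 2 + u * (hi[i] ** 2 - lo[i] ** 2))
            th = rng.uniform(0, 2 * np.pi)
            cand = np.array([cx + r * np.cos(th), cy + r * np.sin(th)])
            d = (
                np.min(np.linalg.norm(pos[:i] - cand, axis=1)) if i else np.inf
            )
            if d >= min_sep:
                best_cand = cand
                break
            if d > best_d:  # fall back to the least-crowded candidate
                best_cand, best_d = cand, d
        pos[i] = best_cand
    return pos, is_peri


def simulate_tracks(
    spec: SyntheticCellSpec, geometry: CellGeometry
) -> tuple[TrackSet, GroundTruth]:
    """Simulate per-frame positions with exactly imposed net displacements.

    For each mitochondrion a net displacement is drawn log-normal, a
    direction is chosen that keeps the endpoint inside the cell and outside
    the nucleus, and the intermediate frames follow a Brownian bridge
    (per-step wiggle ``step_noise_nm``) clamped to the cytoplasmic annulus.
    The region label is taken from the first-frame centroid.
    """
    rng = substream(spec.seed, "tracks")
    n, nf = spec.n_mito, spec.n_frames
    cx, cy = spec.center_nm
    starts, is_peri = _sample_positions(spec, rng)

    gm_peri = spec.geo_mean_displacement
    gm_periph = (
        spec.geo_mean_peripheral
        if spec.geo_mean_peripheral is not None
        else spec.geo_mean_displacement
    )
    mu = np.where(is_peri, np.log(gm_peri), np.log(gm_periph))
    sigma = np.log(spec.geo_sd)
    disps = np.exp(rng.normal(mu, sigma)) if sigma > 0 else np.exp(mu)

    r_min = spec.nucleus_radius + 0.5
    r_max = spec.cell_radius - 0.5
    ends = np.empty_like(starts)
    for i in range(n):
        for _ in range(256):
            ang = rng.uniform(0, 2 * np.pi)
            cand = starts[i] + disps[i] * np.array([np.cos(ang), np.sin(ang)])
            r = np.hypot(cand[0] - cx, cand[1] - cy)
            if r_min < r < r_max:
                ends[i] = cand
                break
        else:  # pragma: no cover - displacements are tiny vs. the annulus
            ends[i] = starts[i]
            disps[i] = 0.0

    # Brownian bridge between start and end, exact at both endpoints
    t = np.linspace(0.0, 1.0, nf)[None, :, None]
    steps = rng.normal(0.0, spec.step_noise_nm, size=(n, nf - 1, 2))
    walk = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    bridge = walk - t * walk[:, -1:, :]
    tracks = starts[:, None, :] + t * (ends - starts)[:, None, :] + bridge

    # clamp interior frames to the cytoplasmic annulus (endpoints untouched)
    rel = tracks - np.array([cx, cy])
    r = np.linalg.norm(rel, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 0, rel / np.maximum(r[..., None], 1e-12), 0.0)
    clamped_r = np.clip(r, r_min, r_max)
    interior = np.zeros_like(r, dtype=bool)
    interior[:, 1:-1] = True
    tracks = np.where(
        (interior & (r != clamped_r))[..., None],
        np.array([cx, cy]) + unit * clamped_r[..., None],
        tracks,
    )

    lengths = rng.uniform(*spec.mito_length_range, size=n)
    widths = np.minimum(rng.uniform(*spec.mito_width_range, size=n), lengths)
    orientations = rng.uniform(0, np.pi, size=n)

    px = spec.pixel_size
    labels = [
        assign_region((tracks[i, 0, 1] / px, tracks[i, 0, 0] / px), geometry.masks)
        for i in range(n)
    ]
    track_list = [
        [
            MitoDetection(
                frame_index=f,
                x_nm=float(tracks[i, f, 0]),
                y_nm=float(tracks[i, f, 1]),
                length_nm=float(lengths[i]),
                width_nm=float(widths[i]),
                region=labels[i],
            )
            for f in range(nf)
        ]
        for i in range(n)
    ]
    truth = GroundTruth(
        tracks=tracks,
        net_displacements=np.linalg.norm(ends - starts, axis=1),
        region_labels=labels,
        dimensions=np.stack([lengths, widths], axis=1),
        orientations=orientations,
    )
    ts = TrackSet(tracks=track_list, frame_interval=spec.frame_interval, n_frames=nf)
    return ts, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Optics:
    """Wide-field rendering parameters.

    ``psf_sigma`` is the Gaussian point-spread sigma in nm; ``snr`` is the
    ratio of the rod core amplitude to the additive noise sd (``inf`` for
    noiseless frames).
    """

    psf_sigma: float = 150.0  # nm
    snr: float = 20.0


def _render_rod(
    frame: np.ndarray,
    center_nm: tuple[float, float],
    theta: float,
    length_nm: float,
    width_nm: float,
    amplitude: float,
    psf_sigma_nm: float,
    pixel_size: float,
    normalize_footprint: bool = False,
) -> None:
    """Add one blurred rod (capsule) to ``frame`` in place.

    The profile is an error-function edge centered on the true capsule
    boundary (the exact profile of a straight edge under Gaussian blur), so
    the half-maximum contour coincides with the true rod outline and the
    intensity pattern is symmetric about the true centroid.  With
    ``normalize_footprint`` the rod is rescaled so that its *mean* added
    intensity over the true capsule footprint equals ``amplitude`` exactly
    (blur moves intensity outside the outline; the rescale puts the
    footprint mean back on contract).
    """
    x0, y0 = center_nm
    half = (length_nm / 2.0 + 4.0 * psf_sigma_nm) / pixel_size + 2
    r_c, c_c = y0 / pixel_size, x0 / pixel_size
    r_lo = max(int(np.floor(r_c - half)), 0)
    r_hi = min(int(np.ceil(r_c + half)) + 1, frame.shape[0])
    c_lo = max(int(np.floor(c_c - half)), 0)
    c_hi = min(int(np.ceil(c_c + half)) + 1, frame.shape[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi].astype(float)
    px_x = cc * pixel_size - x0
    px_y = rr * pixel_size - y0
    # distance to the capsule's axis segment
    ux, uy = np.cos(theta), np.sin(theta)
    half_seg = max(length_nm - width_nm, 0.0) / 2.0
    along = np.clip(px_x * ux + px_y * uy, -half_seg, half_seg)
    d = np.hypot(px_x - along * ux, px_y - along * uy)
    profile = 0.5 * (1.0 + erf((width_nm / 2.0 - d) / (np.sqrt(2) * psf_sigma_nm)))
    if normalize_footprint:
        footprint = d <= width_nm / 2.0
        total = profile[footprint].sum()
        if footprint.any() and total > 0:
            profile = profile * (footprint.sum() / total)
    frame[r_lo:r_hi, c_lo:c_hi] += amplitude * profile


def render_stack(
    tracks: TrackSet,
    geometry: CellGeometry,
    optics: Optics = Optics(),
    *,
    orientations: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render the mitochondria channel: one frame per timepoint.

    Each mitochondrion appears as an oriented Gaussian-edge rod at its
    per-frame centroid with its own length/width; additive Gaussian noise is
    scaled by ``optics.snr``.  Deterministic for a given seed (defaulting to
    the cell spec's seed).
    """
    spec = geometry.spec
    if seed is None:
        seed = spec.seed
    rng = substream(seed, "stack-noise")
    if orientations is None:
        orientations = substream(seed, "stack-orient").uniform(
            0, np.pi, size=len(tracks.tracks)
        )
    stack = np.zeros((tracks.n_frames, *spec.image_shape), dtype=np.float32)
    for i, track in enumerate(tracks.tracks):
        theta = float(orientations[i])
        for det in track:
            _render_rod(
                stack[det.frame_index],
                (det.x_nm, det.y_nm),
                theta,
                det.length_nm,
                det.width_nm,
                amplitude=1.0,
                psf_sigma_nm=optics.psf_sigma,
                pixel_size=spec.pixel_size,
            )
    if np.isfinite(optics.snr):
        stack += rng.normal(0.0, 1.0 / optics.snr, size=stack.shape).astype(np.float32)
    return stack


def stack_metadata(spec: SyntheticCellSpec) -> dict:
    """Acquisition metadata stored alongside rendered stacks."""
    return {
        "n_frames": spec.n_frames,
        "frame_interval_s": spec.frame_interval,
        "epoch_s": spec.epoch_s,
        "pixel_size_nm": spec.pixel_size,
    }


@dataclass
class TmrmScene:
    """A rendered TMRM / nucleus image pair plus its ground truth."""

    tmrm_image: np.ndarray
    nucleus_image: np.ndarray
    mito_mask: np.ndarray  # true (unblurred) mitochondrial footprint
    positions: np.ndarray  # (n, 2) nm
    region_labels: list[str]
    potential: dict[str, float]
    background_level: float


def render_tmrm(
    geometry: CellGeometry,
    regional_potential: dict[str, float],
    background_level: float = 20.0,
    optics: Optics = Optics(),
    *,
    seed: int | None = None,
) -> TmrmScene:
    """Render a single-frame TMRM image with region-dependent rod intensity.

    Mitochondrial pixels in each region have mean intensity
    ``background_level + regional_potential[region]``; everything else sits
    at ``background_level``.  Noise sd is set by ``optics.snr`` relative to
    the largest regional potential (or the background when all potentials
    vanish).
    """
    spec = geometry.spec
    if any(v < 0 for v in regional_potential.values()):
        raise ValueError("regional potentials must be >= 0")
    if seed is None:
        seed = spec.seed
    # layout is a property of the cell (spec seed); the call seed only
    # changes the noise realization
    rng = substream(spec.seed, "tmrm-layout")
    noise_rng = substream(seed, "tmrm-noise")
    pos, is_peri = _sample_positions(spec, rng)
    labels = ["perinuclear" if p else "peripheral" for p in is_peri]
    lengths = rng.uniform(*spec.mito_length_range, size=len(pos))
    widths = np.minimum(rng.uniform(*spec.mito_width_range, size=len(pos)), lengths)
    thetas = rng.uniform(0, np.pi, size=len(pos))

    img = np.full(spec.image_shape, float(background_level), dtype=np.float64)
    mito_mask = np.zeros(spec.image_shape, dtype=bool)
    rr, cc = np.mgrid[0 : spec.image_shape[0], 0 : spec.image_shape[1]].astype(float)
    for i in range(len(pos)):
        amp = float(regional_potential[labels[i]])
        _render_rod(
            img,
            (pos[i, 0], pos[i, 1]),
            float(thetas[i]),
            float(lengths[i]),
            float(widths[i]),
            amplitude=amp,
            psf_sigma_nm=optics.psf_sigma,
            pixel_size=spec.pixel_size,
            normalize_footprint=True,
        )
        # true footprint: pixels within the capsule outline
        ux, uy = np.cos(thetas[i]), np.sin(thetas[i])
        px_x = cc * spec.pixel_size - pos[i, 0]
        px_y = rr * spec.pixel_size - pos[i, 1]
        half_seg = max(lengths[i] - widths[i], 0.0) / 2.0
        along = np.clip(px_x * ux + px_y * uy, -half_seg, half_seg)
        d = np.hypot(px_x - along * ux, px_y - along * uy)
        mito_mask |= d <= widths[i] / 2.0
    ref = max(max(regional_potential.values(), default=0.0), 0.0)
    if ref == 0.0:
        ref = max(background_level, 1.0)
    if np.isfinite(optics.snr):
        img += noise_rng.normal(0.0, ref / optics.snr, size=img.shape)
    return TmrmScene(
        tmrm_image=img.astype(np.float32),
        nucleus_image=geometry.nucleus_image,
        mito_mask=mito_mask,
        positions=pos,
        region_labels=labels,
        potential=dict(regional_potential),
        background_level=float(background_level),
    )


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Parameters of one simulated mito-stress-test plate.

    Stage means are constructed from the mitochondrial truth plus the
    non-mitochondrial OCR; background wells record zero-mean noise only.
    """

    n_wells: int = 10
    n_background_wells: int = 3
    baseline_ocr: float = 100.0  # pmol O2/min (mitochondrial part)
    leak_fraction: float = 0.2  # of baseline
    maximal_factor: float = 2.0  # multiple of baseline
    nonmito_ocr: float = 10.0  # pmol O2/min
    noise_sd: float = 2.0  # pmol O2/min
    measurements_per_stage: int = 3
    cells_per_well: int = 60_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_wells < MIN_BACKGROUND_WELLS:
            raise ValueError(
                f"need at least {MIN_BACKGROUND_WELLS} background wells, "
                f"got {self.n_background_wells}"
            )
        if not 0 <= self.leak_fraction <= 1:
            raise ValueError("leak_fraction must be in [0, 1]")
        if self.maximal_factor < 1:
            raise ValueError("maximal_factor must be >= 1")
        if self.measurements_per_stage < 1:
            raise ValueError("measurements_per_stage must be >= 1")
        if self.n_wells < 1:
            raise ValueError("need at least one cell well")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def stage_means(self) -> dict[str, float]:
        """Observed (uncorrected) OCR mean per stage for a cell well."""
        return {
            "baseline": self.baseline_ocr + self.nonmito_ocr,
            "oligomycin": self.leak_fraction * self.baseline_ocr + self.nonmito_ocr,
            "fccp": self.maximal_factor * self.baseline_ocr + self.nonmito_ocr,
            "rotenone": self.nonmito_ocr,
        }

    def true_parameters(self) -> dict[str, float]:
        """Ground-truth respiration parameters implied by the spec."""
        baseline = self.baseline_ocr
        leak = self.leak_fraction * self.baseline_ocr
        maximal = self.maximal_factor * self.baseline_ocr
        return {
            "baseline": baseline,
            "leak": leak,
            "maximal": maximal,
            "nonmito": self.nonmito_ocr,
            "src": maximal - baseline,
            "atp_linked": baseline - leak,
        }


def simulate_plate(spec: SyntheticPlateSpec) -> tuple[PlateOCR, dict[str, float]]:
    """Simulate a plate run; returns the plate and its ground-truth parameters.

    Each well's trace visits the four stages in injection order with
    ``measurements_per_stage`` points per stage and i.i.d. Gaussian noise of
    sd ``noise_sd``; background wells are zero-mean noise only.
    """
    rng = substream(spec.seed, "plate")
    means = spec.stage_means()
    rows = []
    wells = [f"C{i + 1:02d}" for i in range(spec.n_wells)]
    bg_wells = [f"BG{i + 1:02d}" for i in range(spec.n_background_wells)]
    cycle = 0
    for s_idx, stage in enumerate(STAGES):
        for m in range(spec.measurements_per_stage):
            t = cycle * 390.0  # one measurement cycle ~6.5 min
            for w in wells:
                rows.append((w, stage, m, t, means[stage] + rng.normal(0, spec.noise_sd), 0))
            for w in bg_wells:
                rows.append((w, stage, m, t, rng.normal(0, spec.noise_sd), 1))
            cycle += 1
    df = pd.DataFrame(
        rows,
        columns=["well", "stage", "measurement_index", "time_s", "ocr", "is_background"],
    )
    plate = PlateOCR(
        data=df[["well", "stage", "measurement_index", "time_s", "ocr"]],
        background_wells=frozenset(bg_wells),
        cells_per_well=spec.cells_per_well,
    ).validate()
    return plate, spec.true_parameters()


def write_plate_csv(plate: PlateOCR, path: str | Path) -> Path:
    """Write a plate as tidy CSV (with an ``is_background`` column)."""
    path = Path(path)
    df = plate.data.copy()
    df["is_background"] = df["well"].isin(plate.background_wells).astype(int)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_stack_tiff(
    stack: np.ndarray, spec: SyntheticCellSpec, path: str | Path
) -> Path:
    """Write a time-lapse stack as multi-page TIFF with acquisition metadata."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), metadata=stack_metadata(spec)
    )
    return path


def write_image_tiff(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> Path:
    """JSON sidecar with the exact simulation truth (tracks downsampled to ends)."""
    path = Path(path)
    payload = {
        "net_displacements_nm": truth.net_displacements.tolist(),
        "region_labels": truth.region_labels,
        "dimensions_nm": truth.dimensions.tolist(),
        "first_frame_xy_nm": truth.tracks[:, 0, :].tolist(),
        "last_frame_xy_nm": truth.tracks[:, -1, :].tolist(),
    }
    if truth.potential is not None:
        payload["potential"] = truth.potential
    if truth.resp is not None:
        payload["resp"] = truth.resp
    path.write_text(json.dumps(payload))
    return path
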