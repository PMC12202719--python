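"""Minimal spiral reconstruction and the noise-ratio metric.

Density-compensated adjoint gridding (Kaiser-Bessel interpolation,
2x oversampling, deapodisation) with root-sum-of-squares coil
combination — enough to visualise pilot-tone artifacts and measure
noise statistics, deliberately short of iterative reconstruction.

Density compensation uses Voronoi cell areas of the sampled k-space
points, computed once per trajectory and cached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi
from scipy.special import i0

from .io_core import AcquisitionSet, ReconConfig, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ImageFrame",
    "NoiseRatioResult",
    "grid_recon",
    "view_share_frames",
    "noise_ratio",
    "roi_mask",
]


@dataclass
class ImageFrame:
    """Magnitude image with its geometry and timing."""

    pixels: np.ndarray        # (grid, grid), non-negative magnitude
    fov: float                # FOV side length (same unit as 1/trajectory)
    frame_time: float         # s, centre-line time
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError("image must be square")
        if np.any(self.pixels < 0):
            raise ValidationError("magnitude image must be non-negative")


@dataclass
class NoiseRatioResult:
    """SD ratio between a test and a reference noise-only image."""

    sd_test: float
    sd_ref: float
    ratio: float
    roi_center: tuple[float, float]
    roi_diameter_fraction: float


# ---------------------------------------------------------------------------
# Density compensation
# ---------------------------------------------------------------------------

_dcf_cache: dict[bytes, np.ndarray] = {}


def voronoi_weights(k: np.ndarray) -> np.ndarray:
    """Voronoi-cell-area density compensation for 2D k-space points.

    Duplicate points share their cell's area; unbounded boundary cells
    are clipped to the largest finite cell area.
    """
    pts = np.round(np.asarray(k, dtype=float).reshape(-1, 2), 8)
    key = pts.tobytes()
    if key in _dcf_cache:
        return _dcf_cache[key]
    uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True,
                                      return_counts=True)
    if uniq.shape[0] < 5:
        w = np.ones(pts.shape[0])
    else:
        vor = Voronoi(uniq)
        areas = np.full(uniq.shape[0], np.nan)
        for i, reg_idx in enumerate(vor.point_region):
            region = vor.regions[reg_idx]
            if -1 in region or len(region) < 3:
                continue
            v = vor.vertices[region]
            x, y = v[:, 0], v[:, 1]
            areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        finite = np.isfinite(areas)
        if not finite.any():
            areas[:] = 1.0
        else:
            cap = np.nanmax(areas[finite])
            areas[~finite] = cap
            areas = np.minimum(areas, cap)
        w = areas[inverse] / counts[inverse]
    if len(_dcf_cache) > 64:
        _dcf_cache.clear()
    _dcf_cache[key] = w
    return w


# ---------------------------------------------------------------------------
# Kaiser-Bessel gridding
# ---------------------------------------------------------------------------


def _kb_beta(width: int, oversampling: float) -> float:
    # Beatty et al. choice for minimal aliasing error
    return np.pi * np.sqrt((width / oversampling) ** 2
                           * (oversampling - 0.5) ** 2 - 0.8)


def _kb_kernel(d: np.ndarray, width: int, beta: float) -> np.ndarray:
    x = 2.0 * d / width
    out = np.zeros_like(d, dtype=float)
    inside = np.abs(x) <= 1.0
    out[inside] = i0(beta * np.sqrt(1.0 - x[inside] ** 2))
    return out


def _kb_deapodize(n: int, big: int, width: int, beta: float) -> np.ndarray:
    """1D inverse of the kernel's Fourier transform on the cropped grid."""
    x = np.arange(n) - n / 2
    t = np.pi * width * x / big
    arg = beta ** 2 - t ** 2
    c = np.empty(n)
    pos = arg > 0
    sq = np.sqrt(np.abs(arg))
    c[pos] = np.sinh(sq[pos]) / sq[pos]
    c[~pos] = np.sinc(sq[~pos] / np.pi)
    c /= c.max()
    return 1.0 / np.maximum(c, 1e-3)


def grid_recon(acq: AcquisitionSet, line_idx: np.ndarray | None = None,
               cfg: ReconConfig | None = None) -> ImageFrame:
    """Density-compensated adjoint gridding of a line subset, with
    root-sum-of-squares combination over the imaging coils.

    The FOV is inferred from the trajectory extent:
    ``fov = grid_size / (2 * max|k|)``.
    """
    cfg = cfg or ReconConfig()
    cfg.validate()
    if line_idx is None:
        line_idx = np.arange(acq.n_lines)
    line_idx = np.asarray(line_idx)
    if line_idx.size == 0:
        raise ValidationError("empty line subset")

    traj = acq.trajectory[line_idx].reshape(-1, 2)
    kmax = np.abs(traj).max()
    if kmax <= 0:
        raise ValidationError("degenerate trajectory")
    n = cfg.grid_size
    fov = n / (2.0 * kmax)
    big = int(round(cfg.oversampling * n))
    width = cfg.kernel_width
    beta = _kb_beta(width, cfg.oversampling)

    w = voronoi_weights(traj)
    coils = acq.imaging_coils
    data = acq.samples[line_idx][:, coils, :].transpose(1, 0, 2).reshape(
        coils.size, -1) * w[None, :]

    # continuous coordinates on the oversampled grid, centred
    coords = traj * fov * cfg.oversampling + big / 2.0
    base = np.floor(coords - width / 2.0).astype(int) + 1
    grid = np.zeros((coils.size, big, big), dtype=np.complex128)
    for ox in range(width):
        gx = base[:, 0] + ox
        kx = _kb_kernel(coords[:, 0] - gx, width, beta)
        gxm = np.mod(gx, big)
        for oy in range(width):
            gy = base[:, 1] + oy
            ky = _kb_kernel(coords[:, 1] - gy, width, beta)
            gym = np.mod(gy, big)
            vals = kx * ky
            for c in range(coils.size):
                np.add.at(grid[c], (gym, gxm), data[c] * vals)

    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid, axes=(1, 2)),
                                       axes=(1, 2)), axes=(1, 2))
    lo = (big - n) // 2
    img = img[:, lo:lo + n, lo:lo + n]
    deap = _kb_deapodize(n, big, width, beta)
    img = img * deap[None, :, None] * deap[None, None, :]
    rss = np.sqrt(np.sum(np.abs(img) ** 2, axis=0))

    t_centre = float(np.median(acq.line_time[line_idx]))
    return ImageFrame(pixels=rss, fov=fov, frame_time=t_centre,
                      pixel_size=fov / n)


def view_share_frames(acq: AcquisitionSet, cfg: ReconConfig | None = None
                      ) -> list[ImageFrame]:
    """Sliding-window reconstruction: frame ``j`` spans
    ``footprint_arms`` lines starting at ``j * frame_stride_arms``;
    consecutive frames share k-space lines when the footprint exceeds
    the stride."""
    cfg = cfg or ReconConfig()
    stride, footprint = cfg.frame_stride_arms, cfg.footprint_arms
    if acq.n_lines < footprint:
        raise ValidationError("record shorter than one temporal footprint")
    if stride > footprint:
        logger.warning("stride %d exceeds footprint %d: temporal gaps",
                       stride, footprint)
    n_frames = (acq.n_lines - footprint) // stride + 1
    frames = []
    for j in range(n_frames):
        idx = np.arange(j * stride, j * stride + footprint)
        frames.append(grid_recon(acq, idx, cfg))
    return frames


# ---------------------------------------------------------------------------
# Noise ratio
# ---------------------------------------------------------------------------


def roi_mask(grid_size: int, diameter_fraction: float) -> np.ndarray:
    """Centred circular ROI covering ``diameter_fraction`` of the FOV."""
    r = diameter_fraction * grid_size / 2.0
    x = np.arange(grid_size) - (grid_size - 1) / 2.0
    X, Y = np.meshgrid(x, x)
    return X ** 2 + Y ** 2 <= r ** 2


def noise_ratio(img_test: ImageFrame, img_ref: ImageFrame,
                roi_diameter_fraction: float = 0.53) -> NoiseRatioResult:
    """SD of the test image over a centred circular ROI divided by the
    SD of the reference image over the same ROI; both images must be
    noise-only reconstructions on the same grid."""
    if img_test.pixels.shape != img_ref.pixels.shape:
        raise ValidationError("images must share the grid")
    n = img_test.pixels.shape[0]
    mask = roi_mask(n, roi_diameter_fraction)
    if not mask.any():
        raise ValidationError("ROI does not cover any pixel")
    sd_test = float(img_test.pixels[mask].std(ddof=1))
    sd_ref = float(img_ref.pixels[mask].std(ddof=1))
    if sd_ref == 0:
        raise ValidationError("reference image has zero noise SD")
    return NoiseRatioResult(sd_test=sd_test, sd_ref=sd_ref,
                            ratio=sd_test / sd_ref,
                            roi_center=(n / 2.0, n / 2.0),
                            roi_diameter_fraction=roi_diameter_fraction)
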