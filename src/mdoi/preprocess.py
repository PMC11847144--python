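"""Calibration of raw multisite frames into per-patch reflectance.

Stages mirror a real structured-illumination acquisition: replicate
averaging with dark/background subtraction and flat-field division, HDR
merging of the exposure ladder, illumination-point detection, patch
extraction around each point, and the final intensity-to-reflectance
calibration against the diffusion-model prediction for a uniform reference
medium (per-patch local-sum normalization followed by a global linear
scale + offset least-squares fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import peak_local_max

from .montecarlo import Acquisition
from .rte import RTEModelConfig, reflectance_semi_infinite

__all__ = [
    "FrameSet",
    "CorrectedStack",
    "PatchStack",
    "CalibrationMissingError",
    "correct_frames",
    "merge_uhdr",
    "snr",
    "find_illumination_points",
    "extract_patches",
    "auto_roi_size",
    "calibrate_reflectance",
]

# the acquisition bundle doubles as the raw frame container
FrameSet = Acquisition


class CalibrationMissingError(KeyError):
    """A required dark frame (or other calibration input) is absent."""


class EmptyPatternError(ValueError):
    """No illumination points were detected in a corrected image."""


@dataclass
class CorrectedStack:
    """Replicate-averaged, dark/background/flat-field corrected images.

    ``images[(pattern, exposure)]`` are float arrays (counts); ``saturated``
    marks pixels at full scale in *any* replicate of that exposure.
    """

    images: dict[tuple[int, int], np.ndarray]
    saturated: dict[tuple[int, int], np.ndarray]
    exposures_ms: tuple[float, ...]
    pixel_pitch_mm: tuple[float, float]


@dataclass
class PatchStack:
    """One reflectance patch per illumination point.

    ``point_px`` are the (row, col) image pixels of the illumination maxima;
    each patch of odd size ``roi_size`` is centered on its point.
    ``calibration`` holds the fitted (scale, offset) once
    :func:`calibrate_reflectance` has run; patches are then calibrated
    reflectance, clamped to >= 0.
    """

    patches: np.ndarray               # (n_points, roi, roi)
    point_px: np.ndarray              # (n_points, 2) int
    roi_size: int
    pixel_pitch_mm: tuple[float, float]
    calibration: tuple[float, float] | None = None
    padded: np.ndarray | None = None  # flags for border-clipped patches
    pattern_ids: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return self.patches.shape[0]

    @property
    def center(self) -> int:
        return self.roi_size // 2

    def rho_grid(self) -> np.ndarray:
        """Distance (mm) of every patch pixel from the central source pixel."""
        c = self.center
        pr, pc = self.pixel_pitch_mm
        r = (np.arange(self.roi_size) - c)
        return np.hypot(r[:, None] * pr, r[None, :] * pc)


def correct_frames(frameset: FrameSet) -> CorrectedStack:
    """Average replicates and remove dark, background and flat-field.

    output = (mean(raw) - dark(exposure) - background) / flatfield,
    clamped to >= 0.
    """
    images: dict[tuple[int, int], np.ndarray] = {}
    sat: dict[tuple[int, int], np.ndarray] = {}
    full = frameset.camera.full_scale
    ff = frameset.flatfield
    if np.any(ff <= 0):
        raise ValueError("flat-field map must be strictly positive")
    for (p, e), stack in frameset.frames.items():
        if e not in frameset.dark_frames:
            raise CalibrationMissingError(
                f"no dark frame for exposure index {e}")
        mean_raw = stack.mean(axis=0)
        out = (mean_raw - frameset.dark_frames[e]
               - frameset.background_frame) / ff
        images[(p, e)] = np.clip(out, 0.0, None)
        sat[(p, e)] = stack.max(axis=0) >= full
    return CorrectedStack(images=images, saturated=sat,
                          exposures_ms=frameset.exposures_ms,
                          pixel_pitch_mm=frameset.pixel_pitch_mm)


def merge_uhdr(
    corrected: CorrectedStack,
    pattern: int,
    exposure_indices: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge the exposure ladder into one radiance image (counts per ms).

    Debevec-style merge with an assumed linear response: per pixel the
    radiance estimates value/exposure of the non-saturated exposures are
    averaged with a triangular ("tent") weight favoring mid-range counts.
    Pixels saturated at every exposure get the shortest-exposure estimate
    and are flagged.  Returns (radiance, flagged).  A 16-bit rendering is
    just a linear rescale of the radiance (see :func:`mdoi.io.to_uint16`).
    """
    if exposure_indices is None:
        # drop the longest exposure by default: the standard ladder merges
        # 10/20/40/80 ms out of a 10..160 acquisition
        n = len(corrected.exposures_ms)
        exposure_indices = tuple(range(n - 1)) if n > 2 else tuple(range(n))
    if len(exposure_indices) < 2:
        raise ValueError("HDR merge needs at least two exposures")
    imgs = [corrected.images[(pattern, e)] for e in exposure_indices]
    sats = [corrected.saturated[(pattern, e)] for e in exposure_indices]
    exps = [corrected.exposures_ms[e] for e in exposure_indices]
    shape = imgs[0].shape
    num = np.zeros(shape)
    den = np.zeros(shape)
    top = max(img.max() for img in imgs)
    for img, sat, t in zip(imgs, sats, exps):
        # tent weight over the usable count range, zero where saturated
        wgt = np.where(sat, 0.0, 1.0 - np.abs(img / max(top, 1e-12) - 0.5) * 2.0)
        wgt = np.clip(wgt, 0.0, 1.0)
        wgt = np.where(sat, 0.0, np.maximum(wgt, 1e-6))
        num += wgt * img / t
        den += wgt
    flagged = den == 0.0
    radiance = np.where(flagged, imgs[0] / exps[0], num / np.maximum(den, 1e-300))
    return radiance, flagged


def snr(image: np.ndarray, source_px: tuple[int, int], rho_mm: float,
        pixel_pitch_mm: tuple[float, float],
        bottom_fraction: float = 0.05) -> float:
    """Signal-to-noise ratio in dB at source-detector distance rho.

    SNR = 20 log10(I_rho / I_B') with I_rho the mean intensity on the ring
    at distance rho from the source and I_B' the mean of the image's bottom
    5% intensities.
    """
    rows = np.arange(image.shape[0])[:, None] - source_px[0]
    cols = np.arange(image.shape[1])[None, :] - source_px[1]
    dist = np.hypot(rows * pixel_pitch_mm[0], cols * pixel_pitch_mm[1])
    half = 0.5 * max(pixel_pitch_mm)
    ring = np.abs(dist - rho_mm) <= half
    if not ring.any():
        raise ValueError("ring at rho lies outside the image")
    i_rho = float(image[ring].mean())
    flat = np.sort(image.ravel())
    k = max(1, int(np.floor(bottom_fraction * flat.size)))
    i_bg = float(flat[:k].mean())
    if i_bg <= 0:
        warnings.warn("zero background intensity; SNR is unbounded",
                      stacklevel=2)
        return float("inf")
    return 20.0 * np.log10(i_rho / i_bg)


def find_illumination_points(
    image: np.ndarray,
    min_separation_px: int,
    threshold: float | None = None,
    bottom_fraction: float = 0.05,
    max_points: int | None = None,
) -> np.ndarray:
    """Detect illumination points as thresholded local maxima.

    The default intensity threshold is background mean + 5 background std,
    background being the bottom 5% of intensities.  Maxima closer than
    ``min_separation_px`` are non-maximum-suppressed (brighter wins; exact
    ties resolved toward the lowest (row, col)).  When the pattern design
    is known, ``max_points`` keeps only the brightest that many maxima.
    Returns an (n, 2) int array sorted by (row, col).
    """
    if threshold is None:
        flat = np.sort(image.ravel())
        k = max(1, int(np.floor(bottom_fraction * flat.size)))
        threshold = float(flat[:k].mean() + 5.0 * flat[:k].std())
    peaks = peak_local_max(image, min_distance=int(min_separation_px),
                           threshold_abs=threshold, exclude_border=False)
    if peaks.size == 0:
        raise EmptyPatternError("no illumination points above threshold")
    # deterministic brighter-wins suppression with (row, col) tie-break
    vals = image[peaks[:, 0], peaks[:, 1]]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -vals))
    kept: list[np.ndarray] = []
    for idx in order:
        p = peaks[idx]
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) >= min_separation_px
               for q in kept):
            kept.append(p)
        if max_points is not None and len(kept) >= max_points:
            break
    pts = np.array(sorted(map(tuple, kept)))
    return pts


def auto_roi_size(image: np.ndarray, point_px: tuple[int, int]) -> int:
    """ROI size from a single-point calibration image.

    The broadest centered odd window that still contains positive intensity
    after background subtraction: twice the maximum Chebyshev radius of
    positive pixels around the point, plus one.
    """
    pos = np.argwhere(image > 0)
    if pos.size == 0:
        raise ValueError("no positive intensity around the point")
    cheb = np.max(np.abs(pos - np.asarray(point_px)), axis=1)
    return int(2 * cheb.max() + 1)


def extract_patches(
    image: np.ndarray,
    points: np.ndarray,
    roi_size: int,
    pixel_pitch_mm: tuple[float, float],
    pattern_id: int = 0,
) -> PatchStack:
    """Cut one odd-sized patch per illumination point, point at the center.

    Patches clipped by the image border are zero-padded and flagged.
    Overlapping ROIs trigger a cross-talk warning naming the pairs.
    """
    if roi_size % 2 != 1:
        raise ValueError("roi_size must be odd so the point can be centered")
    points = np.atleast_2d(np.asarray(points, dtype=int))
    half = roi_size // 2
    n = len(points)
    patches = np.zeros((n, roi_size, roi_size), dtype=float)
    padded = np.zeros(n, dtype=bool)
    for i, (r, c) in enumerate(points):
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        rr0, rr1 = max(r0, 0), min(r1, image.shape[0])
        cc0, cc1 = max(c0, 0), min(c1, image.shape[1])
        patches[i, rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = image[rr0:rr1, cc0:cc1]
        padded[i] = (rr0 != r0) or (rr1 != r1) or (cc0 != c0) or (cc1 != c1)
    overlaps = [
        (i, j)
        for i in range(n) for j in range(i + 1, n)
        if max(abs(points[i, 0] - points[j, 0]),
               abs(points[i, 1] - points[j, 1])) < roi_size
    ]
    if overlaps:
        warnings.warn(f"overlapping ROIs (cross-talk risk): {overlaps}",
                      stacklevel=2)
    return PatchStack(patches=patches, point_px=points, roi_size=roi_size,
                      pixel_pitch_mm=tuple(pixel_pitch_mm), padded=padded,
                      pattern_ids=np.full(n, pattern_id))


def calibrate_reflectance(
    stack: PatchStack,
    reference_props,
    config: RTEModelConfig | None = None,
) -> PatchStack:
    """Map local-sum-normalized patch intensities to model reflectance.

    Each patch is normalized by its own sum; a single global (scale,
    offset) is then fitted by linear least squares so that
    scale * I_norm + offset best matches the dipole reflectance of the
    uniform reference medium at each pixel's rho, over the model's rho
    window.  The calibration is applied to every patch (clamped >= 0) and
    stored on the returned stack.
    """
    if config is None:
        config = RTEModelConfig()
    sums = stack.patches.sum(axis=(1, 2))
    if np.any(sums <= 0):
        raise ValueError("patch with non-positive total intensity")
    norm = stack.patches / sums[:, None, None]
    rho = stack.rho_grid()
    sel = (rho >= config.effective_rho_min()) & (rho <= config.rho_max)
    musp_ref = getattr(reference_props, "musp", None)
    if musp_ref is None:
        raise TypeError("reference_props must expose mua and musp")
    r_theory = reflectance_semi_infinite(rho[sel], reference_props.mua,
                                         musp_ref, config)
    # robust fit: average pixels into half-pixel rho rings first (suppresses
    # per-pixel noise), then relative least squares so the decades-spanning
    # R profile is balanced rather than dominated by the near field
    pitch = 0.5 * max(stack.pixel_pitch_mm)
    ring = np.round(rho[sel] / pitch).astype(int)
    xs, ys = [], []
    for k in np.unique(ring):
        in_ring = ring == k
        xs.append(norm[:, sel][:, in_ring].mean())
        ys.append(r_theory[in_ring].mean())
    x = np.asarray(xs)
    y = np.asarray(ys)
    w = 1.0 / y
    design = np.column_stack([x * w, w])
    coef, _, rank, _ = np.linalg.lstsq(design, y * w, rcond=None)
    if rank < 2:
        raise RuntimeError("degenerate reflectance calibration fit")
    scale, offset = float(coef[0]), float(coef[1])
    calibrated = np.clip(scale * norm + offset, 0.0, None)
    return replace(stack, patches=calibrated, calibration=(scale, offset))
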