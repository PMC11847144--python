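"""Back-projection of 2D coefficient maps into calibrated 3D volumes.

Every fitted source-detector pair contributes its (mua, mus) estimate to the
voxels its photons plausibly traversed: the banana visitation map of the
matching exit-distance bin, rotated to the detector's azimuth.  Visitation
density times the bin's reflectance ratio serves as the contribution weight,
discounting rarely traversed, strongly attenuated voxels.  Weighted sums are
accumulated over all pairs, patches and patterns; the voxel estimate is the
weighted mean.  A region-of-analysis (ROA) square around each illumination
point limits the detectors used and thereby the reconstruction depth — a
square of side L supports depth L/4.  Uniformity calibration divides the
merged volume by a featureless reference (or a base-sampling average),
yielding the relative coefficient volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .banana import BananaLUT
from .rte import CoefficientMap2D

__all__ = [
    "ROAConfig",
    "Volume3D",
    "Backprojector",
    "depth_constraint_from_roa",
    "backproject_pair",
    "reconstruct_patch",
    "merge_volumes",
    "uniformity_calibrate",
    "base_sampling_calibration",
    "segment_features",
]


def depth_constraint_from_roa(side_mm: float) -> float:
    """Maximum reconstruction depth (mm) supported by a square ROA.

    The banana sampling depth is about half the source-detector distance,
    and the farthest usable detector sits half a side from the illumination
    point at the ROA center — so depth = side / 4.
    """
    if side_mm <= 0:
        raise ValueError("ROA side must be positive")
    return side_mm / 4.0


@dataclass(frozen=True)
class ROAConfig:
    """Square region of analysis centered on the illumination point."""

    side_mm: float

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ValueError("ROA side must be positive")

    @property
    def depth_constraint_mm(self) -> float:
        return depth_constraint_from_roa(self.side_mm)


@dataclass
class Volume3D:
    """Weighted-accumulator coefficient volume.

    ``mua``/``mus`` hold weighted sums until :meth:`values` divides by the
    accumulated ``weights``; voxels with zero weight are undefined (NaN).
    """

    mua: np.ndarray
    mus: np.ndarray
    weights: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: list = field(default_factory=list)

    @classmethod
    def empty(cls, shape, voxel_size) -> "Volume3D":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape),
                   tuple(voxel_size))

    def values(self, channel: str = "mua") -> np.ndarray:
        """Weighted-mean coefficient per voxel; NaN where unsampled."""
        acc = getattr(self, channel)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.weights > 0, acc / self.weights, np.nan)
        return out

    @property
    def defined(self) -> np.ndarray:
        return self.weights > 0


def _rotated_contribution(lut: BananaLUT, rho: float, azimuth: float,
                          out_half_px: int, out_nz: int,
                          pixel_pitch: tuple[float, float]) -> np.ndarray:
    """Banana weight map for one source-detector pair on the patch grid.

    The LUT map of the bin nearest ``rho`` (times its reflectance ratio) is
    rotated so its +x axis points along ``azimuth`` and resampled onto a
    (2*out_half_px+1)^2 x out_nz grid centered on the source.
    """
    b = lut.nearest_bin(rho)
    m = lut.maps[b] * lut.reflectance_ratio[b]
    ldx, ldy, ldz = lut.voxel_size
    lx0, ly0 = lut.origin_xy
    pr, pc = pixel_pitch
    n = 2 * out_half_px + 1
    c, s = np.cos(azimuth), np.sin(azimuth)
    # output index (i, j) -> patch coords -> rotate by -azimuth -> lut index
    # x_l = ( c*px + s*py), y_l = (-s*px + c*py)
    # px = (i - half)*pr, py = (j - half)*pc
    a00 = c * pr / ldx
    a01 = s * pc / ldx
    a10 = -s * pr / ldy
    a11 = c * pc / ldy
    off_x = (-(a00 + a01) * out_half_px) - lx0 / ldx - 0.5
    off_y = (-(a10 + a11) * out_half_px) - ly0 / ldy - 0.5
    matrix = np.array([[a00, a01, 0.0], [a10, a11, 0.0], [0.0, 0.0, 1.0]])
    offset = np.array([off_x, off_y, 0.0])
    out = ndimage.affine_transform(
        m, matrix, offset=offset, output_shape=(n, n, out_nz),
        order=1, mode="constant", cval=0.0, prefilter=False)
    return np.clip(out, 0.0, None)


def backproject_pair(
    mua: float,
    mus: float,
    rho: float,
    azimuth: float,
    lut: BananaLUT,
    out_half_px: int = 12,
    out_nz: int = 15,
    pixel_pitch: tuple[float, float] = (0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One source-detector pair's contribution in the source-local frame.

    Returns (values_mua, values_mus, weights): weights are the rotated
    visitation map times the bin's reflectance ratio; values are the
    coefficient times the weights, so the weighted mean of a single pair
    returns the coefficient exactly.  Pairs beyond the LUT rho range are
    skipped (all-zero contribution).
    """
    if rho - lut.rho_bins[-1] > 0.5 * (lut.rho_bins[-1] - lut.rho_bins[-2]):
        z = np.zeros((2 * out_half_px + 1, 2 * out_half_px + 1, out_nz))
        return z, z.copy(), z.copy()
    w = _rotated_contribution(lut, rho, azimuth, out_half_px, out_nz,
                              pixel_pitch)
    return mua * w, mus * w, w


class Backprojector:
    """Caches rotated banana contributions per integer detector offset.

    On a regular detector grid the set of (rho, azimuth) pairs inside the
    ROA is the same for every illumination point, so each offset's rotated
    map is computed once and reused across patches and patterns.
    """

    def __init__(self, lut: BananaLUT, roa: ROAConfig,
                 pixel_pitch: tuple[float, float] = (0.5, 0.5),
                 dz: float | None = None):
        self.lut = lut
        self.roa = roa
        self.pixel_pitch = tuple(pixel_pitch)
        self.dz = lut.voxel_size[2] if dz is None else dz
        self.half_px = int(np.floor(0.5 * roa.side_mm / pixel_pitch[0]))
        self.nz = max(1, int(round(roa.depth_constraint_mm / self.dz)))
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        self.skipped_pairs = 0

    def contribution(self, d_row: int, d_col: int) -> np.ndarray | None:
        """Weight map for a detector offset (rows, cols) from the source."""
        key = (d_row, d_col)
        if key in self._cache:
            return self._cache[key]
        pr, pc = self.pixel_pitch
        rho = float(np.hypot(d_row * pr, d_col * pc))
        gap = self.lut.rho_bins[-1] - self.lut.rho_bins[-2] \
            if self.lut.rho_bins.size > 1 else 1.0
        if rho - self.lut.rho_bins[-1] > 0.5 * gap:
            self._cache[key] = None
            return None
        az = float(np.arctan2(d_col * pc, d_row * pr))
        out = _rotated_contribution(self.lut, rho, az, self.half_px,
                                    self.nz, self.pixel_pitch).astype(np.float32)
        self._cache[key] = out
        return out


def reconstruct_patch(
    coeffmap: CoefficientMap2D,
    backprojector: Backprojector,
) -> Volume3D:
    """Accumulate all (source, detector) pairs of one patch into a partial
    volume in the patch-local frame (source at the lateral center, z down).

    Only detector pixels inside the ROA square contribute; voxels deeper
    than the ROA depth constraint are never populated.  With a spatially
    constant coefficient map the weighted mean returns that constant on
    every sampled voxel.
    """
    bp = backprojector
    half = bp.half_px
    n = 2 * half + 1
    vol = Volume3D.empty((n, n, bp.nz), (*bp.pixel_pitch, bp.dz))
    sr, sc = coeffmap.source_pixel
    nr, nc = coeffmap.mua_map.shape
    skipped = 0
    for dr in range(-half, half + 1):
        r = sr + dr
        if r < 0 or r >= nr:
            continue
        for dc in range(-half, half + 1):
            c = sc + dc
            if c < 0 or c >= nc or not coeffmap.valid[r, c]:
                continue
            w = bp.contribution(dr, dc)
            if w is None:
                skipped += 1
                continue
            vol.mua += coeffmap.mua_map[r, c] * w
            vol.mus += coeffmap.mus_map[r, c] * w
            vol.weights += w
    bp.skipped_pairs += skipped
    vol.provenance.append(("patch", coeffmap.patch_id))
    return vol


def merge_volumes(
    partials: list[tuple[Volume3D, tuple[int, int]]],
    out_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> Volume3D:
    """Realign patch-local partial volumes and merge by weighted average.

    ``partials`` pairs each partial with the (row, col) image pixel of its
    source; the partial's lateral center lands on that pixel.  Weighted
    sums simply accumulate, so two identical partials leave the values
    unchanged while doubling the weights.
    """
    out = Volume3D.empty(out_shape, voxel_size)
    for vol, (sr, sc) in partials:
        n0, n1, nz = vol.mua.shape
        half0, half1 = n0 // 2, n1 // 2
        r0, c0 = sr - half0, sc - half1
        rr0, rr1 = max(r0, 0), min(r0 + n0, out_shape[0])
        cc0, cc1 = max(c0, 0), min(c0 + n1, out_shape[1])
        zz = min(nz, out_shape[2])
        src = np.s_[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0, :zz]
        dst = np.s_[rr0:rr1, cc0:cc1, :zz]
        out.mua[dst] += vol.mua[src]
        out.mus[dst] += vol.mus[src]
        out.weights[dst] += vol.weights[src]
        out.provenance.extend(vol.provenance)
    return out


def uniformity_calibrate(volume: Volume3D, calib: Volume3D,
                         method: str = "uniform_phantom") -> Volume3D:
    """Relative coefficient volume: voxel-wise ratio to the calibration.

    The calibration volume comes from a featureless reference
    reconstruction or from base-region sampling of the data itself.  The
    output keeps the input's weights; voxels where the calibration is zero
    or undefined are flagged (NaN values, zero weight).
    """
    v_mua = volume.values("mua")
    v_mus = volume.values("mus")
    c_mua = calib.values("mua")
    c_mus = calib.values("mus")
    ok = volume.defined & calib.defined & (c_mua != 0) & (c_mus != 0)
    n_bad = int((volume.defined & ~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels lack calibration and were flagged",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_mua = np.where(ok, v_mua / c_mua, np.nan)
        rel_mus = np.where(ok, v_mus / c_mus, np.nan)
    w = np.where(ok, volume.weights, 0.0)
    out = Volume3D(rel_mua * w, rel_mus * w, w, volume.voxel_size,
                   provenance=volume.provenance + [("calibrated", method)])
    return out


def base_sampling_calibration(
    partials: list[tuple[Volume3D, tuple[int, int]]],
) -> Volume3D:
    """Calibration volume from the data itself (no reference phantom).

    Assumes most of the sample is featureless base: the patch-local partial
    reconstructions are averaged across all illumination points, giving the
    systematic radial/depth response of a representative base patch.  The
    average patch is then used as the calibration for each partial's
    neighborhood (tile it via :func:`merge_volumes` with the same source
    positions).
    """
    if not partials:
        raise ValueError("need at least one partial volume")
    shape = partials[0][0].mua.shape
    acc = Volume3D.empty(shape, partials[0][0].voxel_size)
    for vol, _ in partials:
        acc.mua += vol.mua
        acc.mus += vol.mus
        acc.weights += vol.weights
    acc.provenance.append(("base_sampling", len(partials)))
    return acc


def segment_features(rel_values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Threshold + largest-connected-component segmentation.

    Stands in for the manual segmentation of reconstructed features:
    voxels brighter than mean + k*std of the defined region, then the
    largest 26-connected component.
    """
    vals = np.asarray(rel_values, dtype=float)
    defined = np.isfinite(vals)
    if not defined.any():
        return np.zeros(vals.shape, dtype=bool)
    thr = np.nanmean(vals) + k * np.nanstd(vals)
    mask = defined & (vals > thr)
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))
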