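"""Photon-visitation ("banana") look-up maps for back-projection.

For a homogeneous half-space the cloud of paths joining a surface source to
a surface detector at distance rho is a banana-shaped probability density —
the system's point-spread function.  ``build_banana_lut`` scores escaped
photon trajectories from the forward Monte Carlo into per-rho-bin 3D
visitation grids in a local frame (source at the origin, exit azimuth
rotated onto +x, which is exact for a homogeneous medium by in-plane
isotropy), averaged over several independent repetitions.  Each bin also
carries a reflectance ratio — the escaped-weight fraction at that exit
distance — used as a depth-attenuation correction weight during
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .montecarlo import _check_phantom
from .phantoms import OpticalProperties, VoxelPhantom, make_phantom

__all__ = ["BananaLUT", "build_banana_lut", "centroid_depth"]

_SEG_CAP = 60_000


@dataclass
class BananaLUT:
    """Per-source-detector-distance photon visitation maps.

    ``maps[b]`` is the visitation density (weight x path length per voxel,
    normalized by launched photons) for exit distances nearest
    ``rho_bins[b]``, on a grid whose voxel (0,0,0) corner sits at
    ``(origin_xy[0], origin_xy[1], 0)`` mm relative to the source, with the
    detector on the +x axis.  ``reflectance_ratio[b]`` is the escaped-weight
    fraction per launched photon in that bin; ``bin_counts[b]`` the photon
    count (zero-count bins are flagged, their maps are zero).
    """

    rho_bins: np.ndarray
    maps: np.ndarray          # (n_bins, lnx, lny, lnz)
    reflectance_ratio: np.ndarray
    bin_counts: np.ndarray
    voxel_size: tuple[float, float, float]
    origin_xy: tuple[float, float]
    bulk_props: OpticalProperties
    n_photons: int
    n_reps: int
    seed: int
    n_flagged: int = 0

    @property
    def flagged_bins(self) -> np.ndarray:
        return self.bin_counts == 0

    def nearest_bin(self, rho: float) -> int:
        return int(np.argmin(np.abs(self.rho_bins - rho)))

    def local_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) of the local map grid."""
        ldx, ldy, ldz = self.voxel_size
        lx0, ly0 = self.origin_xy
        nx, ny, nz = self.maps.shape[1:]
        return (lx0 + (np.arange(nx) + 0.5) * ldx,
                ly0 + (np.arange(ny) + 0.5) * ldy,
                (np.arange(nz) + 0.5) * ldz)


def build_banana_lut(
    bulk_props: OpticalProperties,
    rho_bins: np.ndarray | None = None,
    n_photons: int = 100_000,
    n_reps: int = 5,
    seed: int = 0,
    phantom: VoxelPhantom | None = None,
    local_extent_mm: tuple[float, float, float, float, float] = (-4.0, 12.0, -6.0, 6.0, 6.0),
) -> BananaLUT:
    """Monte-Carlo banana maps for a homogeneous medium.

    ``rho_bins`` defaults to one bin per surface-voxel ring (0.5 mm pitch)
    out to 8.5 mm.  ``local_extent_mm`` is (x_min, x_max, y_min, y_max,
    z_max) of the local scoring grid.  ``n_reps`` independent repetitions
    (distinct RNG streams) are averaged, the default of 5 trading off the
    stochastic jitter of a single run.
    """
    if phantom is None:
        phantom = make_phantom(bulk_props=bulk_props)
    n_rel = _check_phantom(phantom)
    if rho_bins is None:
        rho_bins = np.arange(0.0, 8.51, 0.5)
    rho_bins = np.asarray(rho_bins, dtype=np.float64)
    if rho_bins.ndim != 1 or np.any(np.diff(rho_bins) <= 0):
        raise ValueError("rho_bins must be 1D ascending")
    # exits farther than half a bin pitch beyond the binned range are dropped
    rho_margin = 0.5 * float(np.median(np.diff(rho_bins))) if rho_bins.size > 1 \
        else 0.25
    dx, dy, dz = phantom.voxel_size
    x0, x1, y0, y1, zmax = local_extent_mm
    lnx = int(round((x1 - x0) / dx))
    lny = int(round((y1 - y0) / dy))
    lnz = int(round(zmax / dz))
    ex, ey, _ = phantom.extent_mm
    sx, sy = 0.5 * ex, 0.5 * ey

    maps = np.zeros((rho_bins.size, lnx, lny, lnz), dtype=np.float64)
    refl_ratio = np.zeros(rho_bins.size, dtype=np.float64)
    bin_counts = np.zeros(rho_bins.size, dtype=np.int64)
    refl_map = np.zeros(phantom.shape[:2], dtype=np.float64)
    absorb = np.zeros((1, 1, 1), dtype=np.float64)
    seg_buf = np.zeros((4, _SEG_CAP), dtype=np.float32)

    n_flagged = 0
    rep_seeds = np.random.SeedSequence(int(seed) & 0x7FFFFFFF).generate_state(n_reps)
    for rep in range(n_reps):
        _, _, _, _, nf = _kernels.transport_kernel(
            phantom.mua, phantom.mus, phantom.g, n_rel,
            dx, dy, dz, sx, sy, 0.01,
            int(n_photons), int(rep_seeds[rep]) & 0x7FFFFFFFFFFFFFFF,
            refl_map, absorb, False,
            True, rho_bins, rho_margin, maps, x0, y0, dx, dy, dz,
            refl_ratio, bin_counts, seg_buf,
        )
        n_flagged += int(nf)

    total = float(n_photons) * n_reps
    return BananaLUT(
        rho_bins=rho_bins,
        maps=maps / total,
        reflectance_ratio=refl_ratio / total,
        bin_counts=bin_counts,
        voxel_size=(dx, dy, dz),
        origin_xy=(x0, y0),
        bulk_props=bulk_props,
        n_photons=int(n_photons),
        n_reps=int(n_reps),
        seed=int(seed),
        n_flagged=n_flagged,
    )


def centroid_depth(lut: BananaLUT, rho: float) -> float:
    """Visitation-weighted mean depth of the banana at its mid-plane.

    Takes the x-slab nearest rho/2 of the map for the bin nearest ``rho``
    and returns the z centroid (mm) — for mid-range rho this sits near
    rho/2, the classic half source-detector-distance sampling depth.
    """
    b = lut.nearest_bin(rho)
    xs, _, zs = lut.local_axes()
    m = lut.maps[b]
    ix = int(np.argmin(np.abs(xs - 0.5 * rho)))
    slab = m[ix].sum(axis=0)  # collapse y -> profile over z
    tot = slab.sum()
    if tot <= 0:
        return float("nan")
    return float((slab * zs).sum() / tot)
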