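"""Forward Monte-Carlo photon transport and synthetic multisite acquisition.

``run_mc`` traces weighted photons through a :class:`~mdoi.phantoms.VoxelPhantom`
and returns the diffuse-reflectance map over the surface voxels (the
air-tissue interface voxels act as detectors).  ``forward_acquisition``
wraps it in a linear 12-bit camera model to emulate what a structured-dot
projector + camera platform would record: multi-exposure replicate frames
with dark offset, read noise, shot noise and flat-field unevenness, plus the
matching calibration frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .phantoms import VoxelPhantom

__all__ = [
    "SourceSpec",
    "MCResult",
    "CameraModel",
    "Acquisition",
    "DegenerateMediumError",
    "run_mc",
    "forward_acquisition",
]

_DUMMY_BINS = np.zeros(1, dtype=np.float64)
_DUMMY_MAPS = np.zeros((1, 1, 1, 1), dtype=np.float64)
_DUMMY_SEG = np.zeros((4, 1), dtype=np.float32)


class DegenerateMediumError(ValueError):
    """Raised when the medium cannot scatter (mus = 0 somewhere)."""


@dataclass(frozen=True)
class SourceSpec:
    """Collimated Gaussian beam entering the surface along +z.

    ``position_xy`` in mm on the surface; ``waist`` is the 1/e^2 beam waist
    in mm (small against the voxel size); the wavelength is metadata only —
    transport depends solely on (mua, mus, g, n).
    """

    position_xy: tuple[float, float]
    waist: float = 0.01
    wavelength_nm: float = 680.0

    def __post_init__(self) -> None:
        if self.waist <= 0:
            raise ValueError("beam waist must be positive")


@dataclass
class MCResult:
    """Per-run tallies; all weights are fractions of the launched weight."""

    reflectance_map: np.ndarray  # escaped weight per surface voxel / launched
    reflected_total: float
    transmitted_total: float
    side_loss: float
    absorbed_total: float
    n_photons: int
    seed: int
    source: SourceSpec
    absorption_map: np.ndarray | None = None
    n_flagged: int = 0

    @property
    def weight_sum(self) -> float:
        return (self.reflected_total + self.transmitted_total
                + self.side_loss + self.absorbed_total)


def _check_phantom(phantom: VoxelPhantom) -> float:
    if np.any(phantom.mus <= 0):
        raise DegenerateMediumError("all voxels need mus > 0")
    n_vals = np.unique(phantom.n)
    if n_vals.size != 1:
        raise ValueError("transport assumes a uniform refractive index")
    return float(n_vals[0])


def run_mc(
    phantom: VoxelPhantom,
    source: SourceSpec,
    n_photons: int,
    seed: int,
    score_absorption: bool = False,
) -> MCResult:
    """Simulate diffuse reflectance for one illumination point.

    Deterministic for a given ``seed``: each photon runs on its own
    counter-derived RNG stream.  ``score_absorption`` additionally
    accumulates the deposited weight per voxel (slower on large grids).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    n_rel = _check_phantom(phantom)
    sx, sy = source.position_xy
    ex, ey, _ = phantom.extent_mm
    if not (0.0 <= sx <= ex and 0.0 <= sy <= ey):
        raise ValueError("source position outside the phantom surface")
    dx, dy, dz = phantom.voxel_size
    refl_map = np.zeros(phantom.shape[:2], dtype=np.float64)
    absorb_map = (np.zeros(phantom.shape, dtype=np.float64)
                  if score_absorption else np.zeros((1, 1, 1), dtype=np.float64))
    r, t, s, a, nf = _kernels.transport_kernel(
        phantom.mua, phantom.mus, phantom.g, n_rel,
        dx, dy, dz, sx, sy, source.waist,
        int(n_photons), int(seed) & 0x7FFFFFFFFFFFFFFF,
        refl_map, absorb_map, score_absorption,
        False, _DUMMY_BINS, 0.0, _DUMMY_MAPS, 0.0, 0.0, 1.0, 1.0, 1.0,
        np.zeros(1), np.zeros(1, dtype=np.int64), _DUMMY_SEG,
    )
    inv = 1.0 / n_photons
    return MCResult(
        reflectance_map=refl_map * inv,
        reflected_total=r * inv,
        transmitted_total=t * inv,
        side_loss=s * inv,
        absorbed_total=a * inv,
        n_photons=int(n_photons),
        seed=int(seed),
        source=source,
        absorption_map=absorb_map * inv if score_absorption else None,
        n_flagged=int(nf),
    )


# ---------------------------------------------------------------------------
# synthetic acquisition


@dataclass(frozen=True)
class CameraModel:
    """Linear 12-bit camera + illumination scaling.

    ``gain`` converts (unit reflectance per surface voxel) x (exposure in ms)
    into counts; defaults put the usable patch signal (reflectance per voxel
    from ~5e-2 at the source to ~1e-6 at 8 mm) across the exposure ladder's
    dynamic range the way a consumer CMOS behind a projector would see it.
    """

    gain: float = 1.0e4          # counts per ms per unit reflectance
    dark_offset: float = 100.0   # counts
    read_noise: float = 2.0      # counts rms per frame
    bit_depth: int = 12
    background_level: float = 3.0  # projector light-leak counts (exposure-flat)
    flatfield_amplitude: float = 0.05  # peak-to-center relative unevenness

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class Acquisition:
    """Synthetic multisite acquisition bundle (mirrors a raw data folder).

    ``frames[(p, e)]`` is a (n_replicates, nx, ny) uint16 stack for pattern
    index p and exposure index e; calibration data come with it.
    """

    frames: dict[tuple[int, int], np.ndarray]
    exposures_ms: tuple[float, ...]
    patterns: list[list[tuple[float, float]]]  # illumination points, mm
    dark_frames: dict[int, np.ndarray]         # per exposure index, averaged
    background_frame: np.ndarray               # leak component above dark
    flatfield: np.ndarray                      # mean-1 multiplicative map
    pixel_pitch_mm: tuple[float, float]
    camera: CameraModel
    saturated_everywhere: list[tuple[int, int]] = field(default_factory=list)


def _make_flatfield(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth radial vignetting profile, normalized to mean 1."""
    nx, ny = shape
    x = np.linspace(-1.0, 1.0, nx)[:, None]
    y = np.linspace(-1.0, 1.0, ny)[None, :]
    ff = 1.0 - amplitude * (x**2 + y**2) / 2.0
    return ff / ff.mean()


def forward_acquisition(
    phantom: VoxelPhantom,
    patterns: list[list[tuple[float, float]]],
    camera: CameraModel,
    exposures_ms: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 160.0),
    n_photons: int = 100_000,
    seed: int = 0,
    n_replicates: int = 50,
    waist: float = 0.01,
) -> Acquisition:
    """Emulate a full multisite scan of ``phantom``.

    Each pattern is a list of illumination points (mm).  Per pattern the MC
    reflectance maps of its points are summed (points are assumed spaced far
    enough for minimal cross-talk), scaled by the linear camera model at each
    exposure of the ascending ladder, and sampled ``n_replicates`` times with
    shot + read noise, clipped to the 12-bit range.  The matching averaged
    dark frames, the background (light-leak) frame and the flat-field map are
    returned alongside.
    """
    if sorted(exposures_ms) != list(exposures_ms):
        raise ValueError("exposures must be ascending")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xACF]))
    shape2d = phantom.shape[:2]
    ff = _make_flatfield(shape2d, camera.flatfield_amplitude)
    full = camera.full_scale

    # per-exposure dark frames, averaged over 50 calibration shots
    dark_frames: dict[int, np.ndarray] = {}
    for e in range(len(exposures_ms)):
        stack = camera.dark_offset + rng.normal(
            0.0, camera.read_noise, size=(50, *shape2d))
        dark_frames[e] = np.clip(np.round(stack), 0, full).mean(axis=0)
    # all-mirrors-off background: leak component above dark
    bg_stack = (camera.dark_offset + camera.background_level * ff
                + rng.normal(0.0, camera.read_noise, size=(50, *shape2d)))
    background_frame = np.clip(np.round(bg_stack), 0, full).mean(axis=0) \
        - dark_frames[0]

    frames: dict[tuple[int, int], np.ndarray] = {}
    saturated: list[tuple[int, int]] = []
    mc_seed = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xD1F])
    child_seeds = mc_seed.generate_state(len(patterns) * max(
        len(p) for p in patterns)).reshape(len(patterns), -1)
    for ipat, points in enumerate(patterns):
        refl = np.zeros(shape2d)
        for ipt, pt in enumerate(points):
            res = run_mc(phantom, SourceSpec(pt, waist=waist),
                         n_photons, int(child_seeds[ipat, ipt]) & 0x7FFFFFFF)
            refl += res.reflectance_map
        for e, exp_ms in enumerate(exposures_ms):
            signal = camera.gain * exp_ms * refl * ff \
                + camera.background_level * ff
            shot = rng.poisson(
                np.broadcast_to(signal, (n_replicates, *shape2d))).astype(np.float64)
            raw = shot + camera.dark_offset \
                + rng.normal(0.0, camera.read_noise, size=(n_replicates, *shape2d))
            frames[(ipat, e)] = np.clip(np.round(raw), 0, full).astype(np.uint16)
        # a pixel saturated across the whole ladder can never be merged
        sat = np.ones(shape2d, dtype=bool)
        for e in range(len(exposures_ms)):
            sat &= frames[(ipat, e)].min(axis=0) >= full
        if sat.any():
            saturated.append((ipat, int(sat.sum())))
    if saturated:
        import warnings
        warnings.warn(
            f"pixels saturated at every exposure in patterns {saturated}",
            stacklevel=2)
    return Acquisition(
        frames=frames,
        exposures_ms=tuple(float(e) for e in exposures_ms),
        patterns=[list(map(tuple, p)) for p in patterns],
        dark_frames=dark_frames,
        background_frame=background_frame,
        flatfield=ff,
        pixel_pitch_mm=(phantom.voxel_size[0], phantom.voxel_size[1]),
        camera=camera,
        saturated_everywhere=saturated,
    )
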