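"""Digital voxel phantoms of dermis-like tissue with embedded pigment features.

The phantom is a regular voxel grid of optical properties (absorption mua,
scattering mus, anisotropy g, refractive index n) with the air-tissue
interface at z = 0 and depth increasing into the medium.  Voxel indices are
0-based; the physical position of a voxel is its center,
``(index + 0.5) * voxel_size``.  Feature membership is decided by a
center-inside-solid test, matching the binary ground-truth masks used for
quantitative evaluation.

Two feature geometries cover melanoma-like test objects: a surface spherical
cap (the intersection of a sphere with the tissue half-space, flat face on
the surface, deepest point at ``depth_bottom``) and a vertical subsurface
cylinder spanning ``[depth_top, depth_bottom]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "FeatureSpec",
    "VoxelPhantom",
    "InvalidGeometryError",
    "make_phantom",
    "add_feature",
    "dermis_properties",
    "DERMIS_MUA",
    "PIGMENT_MUA",
    "SKIN_MUS",
    "DEFAULT_G",
    "DEFAULT_N",
]

# Dermis / pigment optical parameters at red-light illumination (680 nm),
# driven by melanin volume fraction (0% dermis, 20% pigmented feature).
DERMIS_MUA = 0.04     # / mm
PIGMENT_MUA = 4.879   # / mm
SKIN_MUS = 29.411     # / mm, melanin-independent
DEFAULT_G = 0.9       # typical dermis anisotropy
DEFAULT_N = 1.4       # typical soft-tissue refractive index


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or features outside the phantom."""


class UnsupportedValueError(ValueError):
    """Raised when a tabulated tissue parameter is requested outside the table."""


@dataclass(frozen=True)
class OpticalProperties:
    """Per-voxel optical properties.

    mua, mus are per mm; g is the scattering anisotropy in [-1, 1]; n >= 1.
    """

    mua: float
    mus: float
    g: float = DEFAULT_G
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus * (1 - g), per mm."""
        return self.mus * (1.0 - self.g)

    @property
    def mut(self) -> float:
        """Total interaction coefficient mua + mus, per mm."""
        return self.mua + self.mus


@dataclass(frozen=True)
class FeatureSpec:
    """Geometric description of an embedded feature.

    ``kind`` is ``"surface_hemisphere"`` (spherical cap, flat face at z=0,
    deepest point at depth_bottom) or ``"subsurface_cylinder"`` (vertical
    axis, spanning depth_top..depth_bottom).  Lengths in mm.
    """

    kind: str
    radius: float
    depth_bottom: float
    props: OpticalProperties
    center_xy: tuple[float, float]
    depth_top: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("surface_hemisphere", "subsurface_cylinder"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.depth_top < 0 or self.depth_bottom < self.depth_top:
            raise ValueError("need depth_bottom >= depth_top >= 0")


@dataclass
class VoxelPhantom:
    """Voxel grid of optical properties plus a binary ground-truth mask."""

    mua: np.ndarray
    mus: np.ndarray
    g: np.ndarray
    n: np.ndarray
    feature_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    features: list[FeatureSpec] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mua.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical center coordinates along one axis, mm."""
        return (np.arange(self.shape[axis]) + 0.5) * self.voxel_size[axis]

    def bulk_properties(self) -> OpticalProperties:
        """Properties of the (majority) background voxels."""
        bg = ~self.feature_mask.astype(bool)
        if not bg.any():
            bg = np.ones_like(bg)
        idx = np.argwhere(bg)[0]
        i, j, k = idx
        return OpticalProperties(
            float(self.mua[i, j, k]), float(self.mus[i, j, k]),
            float(self.g[i, j, k]), float(self.n[i, j, k]))

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            self.mua.copy(), self.mus.copy(), self.g.copy(), self.n.copy(),
            self.feature_mask.copy(), self.voxel_size, list(self.features))


def make_phantom(
    extent_mm: tuple[float, float, float] = (30.0, 30.0, 10.0),
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.2),
    bulk_props: OpticalProperties | None = None,
) -> VoxelPhantom:
    """Create a homogeneous phantom of the given physical extent.

    The default geometry is a 30 x 30 x 10 mm dermis block at
    0.5 x 0.5 x 0.2 mm voxels (shape 60 x 60 x 50).
    """
    if any(e <= 0 for e in extent_mm) or any(v <= 0 for v in voxel_size):
        raise InvalidGeometryError("extent and voxel size must be positive")
    if bulk_props is None:
        bulk_props = dermis_properties(0.0)
    shape = tuple(int(round(e / v)) for e, v in zip(extent_mm, voxel_size))
    if any(s < 1 for s in shape):
        raise InvalidGeometryError(f"degenerate grid shape {shape}")
    return VoxelPhantom(
        mua=np.full(shape, bulk_props.mua, dtype=np.float64),
        mus=np.full(shape, bulk_props.mus, dtype=np.float64),
        g=np.full(shape, bulk_props.g, dtype=np.float64),
        n=np.full(shape, bulk_props.n, dtype=np.float64),
        feature_mask=np.zeros(shape, dtype=bool),
        voxel_size=tuple(float(v) for v in voxel_size),
    )


def _feature_membership(phantom: VoxelPhantom, spec: FeatureSpec) -> np.ndarray:
    dx, dy, dz = phantom.voxel_size
    xs = phantom.voxel_centers(0)
    ys = phantom.voxel_centers(1)
    zs = phantom.voxel_centers(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    cx, cy = spec.center_xy
    if spec.kind == "surface_hemisphere":
        # sphere centered at depth (depth_bottom - radius); the in-tissue part
        # is a cap of height depth_bottom
        zc = spec.depth_bottom - spec.radius
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - zc) ** 2 <= spec.radius**2
        inside &= Z >= 0.0
    else:
        inside = (X - cx) ** 2 + (Y - cy) ** 2 <= spec.radius**2
        inside &= (Z >= spec.depth_top) & (Z <= spec.depth_bottom)
    return inside


def add_feature(phantom: VoxelPhantom, spec: FeatureSpec) -> VoxelPhantom:
    """Return a copy of the phantom with the feature stamped in.

    Voxels whose centers fall inside the feature solid receive the feature's
    optical properties and are set in the ground-truth mask.
    """
    ex, ey, ez = phantom.extent_mm
    cx, cy = spec.center_xy
    if not (0 <= cx <= ex and 0 <= cy <= ey):
        raise InvalidGeometryError("feature center outside the phantom surface")
    if spec.depth_bottom > ez:
        raise InvalidGeometryError("feature deeper than the phantom")
    out = phantom.copy()
    inside = _feature_membership(phantom, spec)
    out.mua[inside] = spec.props.mua
    out.mus[inside] = spec.props.mus
    out.g[inside] = spec.props.g
    out.n[inside] = spec.props.n
    out.feature_mask |= inside
    out.features.append(spec)
    if out.feature_mask.sum() > 0.5 * out.feature_mask.size:
        warnings.warn(
            "feature occupies more than half the phantom volume; segmentation "
            "guidelines assume a minority feature", stacklevel=2)
    return out


def dermis_properties(melanin_fraction: float,
                      g: float = DEFAULT_G, n: float = DEFAULT_N) -> OpticalProperties:
    """Tabulated dermis optical properties under red light.

    Only the two melanin volume fractions used by the study phantoms are
    tabulated: 0 (plain dermis, mua 0.04/mm) and 0.2 (pigmented feature,
    mua 4.879/mm); mus is 29.411/mm in both cases.
    """
    table = {0.0: DERMIS_MUA, 0.2: PIGMENT_MUA}
    if melanin_fraction not in table:
        raise UnsupportedValueError(
            f"no tabulated properties for melanin fraction {melanin_fraction}; "
            "construct OpticalProperties explicitly")
    return OpticalProperties(mua=table[melanin_fraction], mus=SKIN_MUS, g=g, n=n)
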