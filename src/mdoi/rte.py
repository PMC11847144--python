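"""Steady-state semi-infinite diffuse reflectance model and coefficient fitting.

The spatially resolved reflectance R(rho) of a semi-infinite turbid medium is
modeled with the standard extrapolated-boundary dipole solution of the
diffusion approximation (Farrell-type):

    mut' = mua + mus'          z0 = 1/mut'        D = 1/(3 mut')
    mueff = sqrt(3 mua mut')   zb = 2 A D
    r1 = sqrt(rho^2 + z0^2)    r2 = sqrt(rho^2 + (z0 + 2 zb)^2)
    R(rho) = (1/4pi) [ z0 (mueff + 1/r1) e^{-mueff r1} / r1^2
                     + (z0 + 2 zb)(mueff + 1/r2) e^{-mueff r2} / r2^2 ]

with the internal-reflection parameter A computed from the relative
refractive index via the Groenhuis polynomial approximation.  Fitting is a
bounded trust-region Levenberg-Marquardt least-squares on log R (the signal
spans decades over rho).  The free scattering parameter is the *reduced*
coefficient mus'; reported full-scattering maps are mus'/(1-g) for the
configured anisotropy, since diffusion theory constrains only mus'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RTEModelConfig",
    "ReflectanceProfile",
    "CoefficientMap2D",
    "boundary_parameter_A",
    "reflectance_semi_infinite",
    "fit_cross_section",
    "fit_patch",
]


def boundary_parameter_A(n_rel: float) -> float:
    """Internal-reflection boundary parameter A(n) (Groenhuis polynomial).

    A = (1 + r_d) / (1 - r_d) with
    r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n.
    """
    if n_rel <= 0:
        raise ValueError("relative refractive index must be positive")
    if n_rel == 1.0:
        return 1.0
    r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass(frozen=True)
class RTEModelConfig:
    """Model/fit configuration.

    rho window in mm; bounds and initial guess for (mua, mus'), per mm.
    ``rho_min`` defaults to one transport mean free path of the initial
    guess (diffusion validity); ``rho_max`` to 5 mm, half the distance at
    which the measured signal drops into the noise floor.
    """

    n_rel: float = 1.4
    rho_min: float | None = None
    rho_max: float = 5.0
    init: tuple[float, float] = (0.1, 3.0)
    bounds_mua: tuple[float, float] = (1.0e-4, 10.0)
    bounds_musp: tuple[float, float] = (0.05, 20.0)
    g: float = 0.9  # used only to report full mus = mus'/(1-g)

    @property
    def A(self) -> float:
        return boundary_parameter_A(self.n_rel)

    def effective_rho_min(self) -> float:
        if self.rho_min is not None:
            return self.rho_min
        return 1.0 / (self.init[0] + self.init[1])


@dataclass
class ReflectanceProfile:
    """(rho, R) samples for one cross-section fit."""

    rho: np.ndarray
    R: np.ndarray
    direction: str = "horizontal"

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.rho.shape != self.R.shape:
            raise ValueError("rho and R must align")
        if np.any(self.rho <= 0):
            raise ValueError("rho must be strictly positive")


@dataclass
class FitResult:
    mua: float
    musp: float
    residual: float
    ok: bool
    message: str = ""


@dataclass
class CoefficientMap2D:
    """Per-pixel fitted coefficient maps for one illumination patch.

    ``mua_map``/``mus_map`` per mm (mus is the full coefficient
    mus'/(1-g)); ``fit_error_map`` holds the residual norm; ``valid`` flags
    pixels where at least one direction fit converged.
    """

    mua_map: np.ndarray
    mus_map: np.ndarray
    fit_error_map: np.ndarray
    valid: np.ndarray
    patch_id: int = 0
    source_pixel: tuple[int, int] = (0, 0)
    pixel_pitch_mm: tuple[float, float] = (0.5, 0.5)
    g: float = 0.9

    @property
    def musp_map(self) -> np.ndarray:
        """Reduced scattering map mus' = mus * (1 - g), per mm."""
        return self.mus_map * (1.0 - self.g)


def reflectance_semi_infinite(
    rho: np.ndarray | float,
    mua: float,
    musp: float,
    config: RTEModelConfig | None = None,
) -> np.ndarray | float:
    """Dipole diffuse reflectance R(rho) per mm^2 for a semi-infinite medium."""
    if config is None:
        config = RTEModelConfig()
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0) or mua <= 0 or musp <= 0:
        raise ValueError("rho, mua and mus' must be strictly positive")
    mutp = mua + musp
    z0 = 1.0 / mutp
    D = 1.0 / (3.0 * mutp)
    mueff = np.sqrt(3.0 * mua * mutp)
    zb = 2.0 * config.A * D
    r1 = np.sqrt(rho_arr**2 + z0**2)
    r2 = np.sqrt(rho_arr**2 + (z0 + 2.0 * zb) ** 2)
    out = (z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
           + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
           ) / (4.0 * np.pi)
    return out if isinstance(rho, np.ndarray) else float(out)


def fit_cross_section(
    profile: ReflectanceProfile,
    config: RTEModelConfig | None = None,
) -> FitResult:
    """Fit (mua, mus') to one reflectance cross-section.

    Bounded trust-region least squares on log R over the configured rho
    window; requires at least 4 usable (rho, R) pairs with R > 0.
    """
    if config is None:
        config = RTEModelConfig()
    lo = config.effective_rho_min()
    sel = (profile.rho >= lo) & (profile.rho <= config.rho_max) & (profile.R > 0)
    rho = profile.rho[sel]
    R = profile.R[sel]
    if rho.size < 4:
        return FitResult(np.nan, np.nan, np.inf, False, "insufficient data")
    logR = np.log(R)

    def resid(p):
        return np.log(reflectance_semi_infinite(rho, p[0], p[1], config)) - logR

    lb = [config.bounds_mua[0], config.bounds_musp[0]]
    ub = [config.bounds_mua[1], config.bounds_musp[1]]
    x0 = np.clip(config.init, lb, ub)
    try:
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=200)
    except Exception as exc:  # pragma: no cover - defensive
        return FitResult(np.nan, np.nan, np.inf, False, str(exc))
    res_norm = float(np.sqrt(np.mean(sol.fun**2)))
    return FitResult(float(sol.x[0]), float(sol.x[1]), res_norm,
                     bool(sol.success), sol.message)


def _band_profile(patch, source_px, pixel_pitch, row, col, direction,
                  half_width):
    """(rho, R) pairs from a band of rows (or columns) through a pixel."""
    sr, sc = source_px
    pr, pc = pixel_pitch
    if direction == "horizontal":
        r0 = max(0, row - half_width)
        r1 = min(patch.shape[0], row + half_width + 1)
        sub = patch[r0:r1, :]
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(patch.shape[1])[None, :]
    else:
        c0 = max(0, col - half_width)
        c1 = min(patch.shape[1], col + half_width + 1)
        sub = patch[:, c0:c1]
        rows = np.arange(patch.shape[0])[:, None]
        cols = np.arange(c0, c1)[None, :]
    rho = np.hypot((rows - sr) * pr, (cols - sc) * pc)
    return rho.ravel(), sub.ravel()


def fit_patch(
    patch: np.ndarray,
    source_px: tuple[int, int],
    config: RTEModelConfig | None = None,
    pixel_pitch_mm: tuple[float, float] = (0.5, 0.5),
    half_width: int = 1,
    patch_id: int = 0,
) -> CoefficientMap2D:
    """Per-pixel optical-coefficient maps for one calibrated patch.

    Under the quasi-homogeneity assumption each pixel's coefficients are
    estimated from the (rho, R) pairs of a horizontal and a vertical band
    of half-width ``half_width`` through it (rho measured to the patch's
    source point), fitted independently, then averaged.  Because the band
    depends only on the pixel's row (horizontal) or column (vertical), one
    fit per row and per column covers the whole patch.
    """
    if config is None:
        config = RTEModelConfig()
    patch = np.asarray(patch, dtype=float)
    nr, nc = patch.shape
    row_fits = []
    for r in range(nr):
        rho, R = _band_profile(patch, source_px, pixel_pitch_mm, r, 0,
                               "horizontal", half_width)
        row_fits.append(fit_cross_section(
            _safe_profile(rho, R, "horizontal"), config))
    col_fits = []
    for c in range(nc):
        rho, R = _band_profile(patch, source_px, pixel_pitch_mm, 0, c,
                               "vertical", half_width)
        col_fits.append(fit_cross_section(
            _safe_profile(rho, R, "vertical"), config))

    mua = np.full((nr, nc), np.nan)
    musp = np.full((nr, nc), np.nan)
    err = np.full((nr, nc), np.inf)
    valid = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            cands = [f for f in (row_fits[r], col_fits[c]) if f.ok]
            if not cands:
                continue
            mua[r, c] = float(np.mean([f.mua for f in cands]))
            musp[r, c] = float(np.mean([f.musp for f in cands]))
            err[r, c] = float(np.mean([f.residual for f in cands]))
            valid[r, c] = True
    if not valid.any():
        warnings.warn(f"patch {patch_id}: all pixel fits failed", stacklevel=2)
    return CoefficientMap2D(
        mua_map=mua,
        mus_map=musp / (1.0 - config.g),
        fit_error_map=err,
        valid=valid,
        patch_id=patch_id,
        source_pixel=tuple(source_px),
        pixel_pitch_mm=tuple(pixel_pitch_mm),
        g=config.g,
    )


def _safe_profile(rho, R, direction):
    """Profile builder tolerating the rho=0 source pixel (dropped)."""
    keep = rho > 0
    return ReflectanceProfile(rho[keep], R[keep], direction)
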