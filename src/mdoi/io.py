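"""File containers: HDF5 for volumetric data, TIFF + JSON for imagery.

Phantoms, banana LUTs and reconstructed volumes round-trip bit-exactly
through HDF5 groups.  Acquisition frames export to one multi-page TIFF per
(pattern, exposure) with a JSON sidecar manifest describing the ladder,
patterns and calibration files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .banana import BananaLUT
from .montecarlo import Acquisition, CameraModel
from .phantoms import OpticalProperties, VoxelPhantom
from .recon import Volume3D

__all__ = [
    "save_phantom", "load_phantom",
    "save_lut", "load_lut",
    "save_volume", "load_volume",
    "save_coefficient_maps", "load_coefficient_maps",
    "export_acquisition", "load_acquisition",
    "export_volume_tiff", "to_uint16",
]


def _as_group(handle, mode):
    if isinstance(handle, (str, Path)):
        return h5py.File(handle, mode), True
    return handle, False


def save_phantom(path, phantom: VoxelPhantom) -> None:
    """Write a phantom as an HDF5 group (datasets mua/mus/g/n/feature_mask)."""
    f, own = _as_group(path, "w")
    try:
        for name in ("mua", "mus", "g", "n"):
            f.create_dataset(name, data=getattr(phantom, name))
        f.create_dataset("feature_mask",
                         data=phantom.feature_mask.astype(np.uint8))
        f.attrs["voxel_size"] = phantom.voxel_size
        f.attrs["shape"] = phantom.shape
    finally:
        if own:
            f.close()


def load_phantom(path) -> VoxelPhantom:
    f, own = _as_group(path, "r")
    try:
        return VoxelPhantom(
            mua=f["mua"][()], mus=f["mus"][()], g=f["g"][()], n=f["n"][()],
            feature_mask=f["feature_mask"][()].astype(bool),
            voxel_size=tuple(f.attrs["voxel_size"]),
        )
    finally:
        if own:
            f.close()


def save_lut(path, lut: BananaLUT) -> None:
    f, own = _as_group(path, "w")
    try:
        f.create_dataset("rho_bins", data=lut.rho_bins)
        f.create_dataset("maps", data=lut.maps)
        f.create_dataset("reflectance_ratio", data=lut.reflectance_ratio)
        f.create_dataset("bin_counts", data=lut.bin_counts)
        f.attrs["voxel_size"] = lut.voxel_size
        f.attrs["origin_xy"] = lut.origin_xy
        f.attrs["props"] = (lut.bulk_props.mua, lut.bulk_props.mus,
                            lut.bulk_props.g, lut.bulk_props.n)
        f.attrs["n_photons"] = lut.n_photons
        f.attrs["n_reps"] = lut.n_reps
        f.attrs["seed"] = lut.seed
        f.attrs["n_flagged"] = lut.n_flagged
    finally:
        if own:
            f.close()


def load_lut(path) -> BananaLUT:
    f, own = _as_group(path, "r")
    try:
        p = f.attrs["props"]
        return BananaLUT(
            rho_bins=f["rho_bins"][()],
            maps=f["maps"][()],
            reflectance_ratio=f["reflectance_ratio"][()],
            bin_counts=f["bin_counts"][()],
            voxel_size=tuple(f.attrs["voxel_size"]),
            origin_xy=tuple(f.attrs["origin_xy"]),
            bulk_props=OpticalProperties(*map(float, p)),
            n_photons=int(f.attrs["n_photons"]),
            n_reps=int(f.attrs["n_reps"]),
            seed=int(f.attrs["seed"]),
            n_flagged=int(f.attrs["n_flagged"]),
        )
    finally:
        if own:
            f.close()


def save_volume(path, vol: Volume3D) -> None:
    f, own = _as_group(path, "w")
    try:
        f.create_dataset("mua", data=vol.mua)
        f.create_dataset("mus", data=vol.mus)
        f.create_dataset("weights", data=vol.weights)
        f.attrs["voxel_size"] = vol.voxel_size
        f.attrs["provenance"] = json.dumps(vol.provenance)
    finally:
        if own:
            f.close()


def load_volume(path) -> Volume3D:
    f, own = _as_group(path, "r")
    try:
        return Volume3D(
            mua=f["mua"][()], mus=f["mus"][()], weights=f["weights"][()],
            voxel_size=tuple(f.attrs["voxel_size"]),
            provenance=[tuple(p) for p in json.loads(f.attrs["provenance"])],
        )
    finally:
        if own:
            f.close()


def save_coefficient_maps(path, maps, point_px) -> None:
    """Serialize per-patch fitted coefficient maps (one HDF5 group each)."""
    from .rte import CoefficientMap2D  # noqa: F401 (documented type)
    f, own = _as_group(path, "w")
    try:
        for i, m in enumerate(maps):
            g = f.create_group(f"patch{i:04d}")
            g.create_dataset("mua_map", data=m.mua_map)
            g.create_dataset("mus_map", data=m.mus_map)
            g.create_dataset("fit_error_map", data=m.fit_error_map)
            g.create_dataset("valid", data=m.valid.astype(np.uint8))
            g.attrs["patch_id"] = m.patch_id
            g.attrs["source_pixel"] = m.source_pixel
            g.attrs["pixel_pitch_mm"] = m.pixel_pitch_mm
            g.attrs["g"] = m.g
            g.attrs["point_px"] = tuple(int(v) for v in point_px[i])
    finally:
        if own:
            f.close()


def load_coefficient_maps(path):
    """Returns (list of CoefficientMap2D, (n, 2) array of image points)."""
    from .rte import CoefficientMap2D
    f, own = _as_group(path, "r")
    try:
        maps, points = [], []
        for name in sorted(f.keys()):
            g = f[name]
            maps.append(CoefficientMap2D(
                mua_map=g["mua_map"][()], mus_map=g["mus_map"][()],
                fit_error_map=g["fit_error_map"][()],
                valid=g["valid"][()].astype(bool),
                patch_id=int(g.attrs["patch_id"]),
                source_pixel=tuple(int(v) for v in g.attrs["source_pixel"]),
                pixel_pitch_mm=tuple(g.attrs["pixel_pitch_mm"]),
                g=float(g.attrs["g"]),
            ))
            points.append(tuple(int(v) for v in g.attrs["point_px"]))
        return maps, np.array(points)
    finally:
        if own:
            f.close()


def to_uint16(image: np.ndarray) -> np.ndarray:
    """Linear rescale of a non-negative image onto the 16-bit range."""
    img = np.asarray(image, dtype=float)
    top = np.nanmax(img)
    if not np.isfinite(top) or top <= 0:
        return np.zeros(img.shape, dtype=np.uint16)
    return np.clip(np.round(img / top * 65535.0), 0, 65535).astype(np.uint16)


def export_volume_tiff(path, vol: Volume3D, channel: str = "mua") -> None:
    """16-bit z-stack rendering of a volume for external viewers.

    Undefined voxels render as 0; values are linearly rescaled per volume.
    """
    vals = vol.values(channel)
    vals = np.nan_to_num(vals, nan=0.0)
    stack = to_uint16(vals)
    # z as the page axis
    tifffile.imwrite(path, np.moveaxis(stack, 2, 0))


def export_acquisition(directory, acq: Acquisition) -> Path:
    """Write raw frames as multi-page TIFFs plus a JSON manifest.

    One TIFF per (pattern, exposure) holding the replicate stack, plus
    dark/background/flat-field TIFFs; the manifest records file names,
    exposure times, pattern point coordinates and the camera model.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for (p, e), stack in acq.frames.items():
        name = f"pattern{p:03d}_exp{e}.tif"
        tifffile.imwrite(directory / name, stack)
        entries.append({"pattern": p, "exposure_index": e,
                        "exposure_ms": acq.exposures_ms[e], "file": name,
                        "replicates": int(stack.shape[0])})
    for e, frame in acq.dark_frames.items():
        tifffile.imwrite(directory / f"dark_exp{e}.tif",
                         frame.astype(np.float32))
    tifffile.imwrite(directory / "background.tif",
                     acq.background_frame.astype(np.float32))
    tifffile.imwrite(directory / "flatfield.tif",
                     acq.flatfield.astype(np.float32))
    manifest = {
        "exposures_ms": list(acq.exposures_ms),
        "patterns": [[list(pt) for pt in pat] for pat in acq.patterns],
        "pixel_pitch_mm": list(acq.pixel_pitch_mm),
        "camera": {
            "gain": acq.camera.gain,
            "dark_offset": acq.camera.dark_offset,
            "read_noise": acq.camera.read_noise,
            "bit_depth": acq.camera.bit_depth,
            "background_level": acq.camera.background_level,
            "flatfield_amplitude": acq.camera.flatfield_amplitude,
        },
        "frames": entries,
    }
    mpath = directory / "acquisition.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_acquisition(manifest_path) -> Acquisition:
    """Rebuild an acquisition bundle from a manifest directory."""
    mpath = Path(manifest_path)
    directory = mpath.parent
    m = json.loads(mpath.read_text())
    camera = CameraModel(**m["camera"])
    frames = {}
    for entry in m["frames"]:
        stack = tifffile.imread(directory / entry["file"])
        if stack.ndim == 2:
            stack = stack[None]
        frames[(entry["pattern"], entry["exposure_index"])] = stack
    dark = {}
    for e in range(len(m["exposures_ms"])):
        p = directory / f"dark_exp{e}.tif"
        if p.exists():
            dark[e] = tifffile.imread(p)
    return Acquisition(
        frames=frames,
        exposures_ms=tuple(m["exposures_ms"]),
        patterns=[[tuple(pt) for pt in pat] for pat in m["patterns"]],
        dark_frames=dark,
        background_frame=tifffile.imread(directory / "background.tif"),
        flatfield=tifffile.imread(directory / "flatfield.tif"),
        pixel_pitch_mm=tuple(m["pixel_pitch_mm"]),
        camera=camera,
    )
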