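"""File formats: NIfTI image/label volumes, HDF5 k-space, YAML sidecars.

Dynamic series are stored as 4D NIfTI volumes with shape (x, y, 1, t) and a
YAML sidecar holding fps, FOV and provenance; region masks as an unsigned
integer label volume (0 = background) plus the region-name order; k-space
and acquisitions in HDF5 with real/imaginary channel datasets and a
convention tag (centred grid, DC at N//2, negative-exponent forward).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import DynamicImageSeries, Geometry, KSpaceSeries, RegionMaskSeries
from .sampling import MultiCoilKSpace
from .segmentation import RoiSpec
from .trajectories import Trajectory

CONVENTION = "centred; DC at N//2; forward exp(-i2pi k.x); k in cycles/pixel"


def _nifti_affine(geometry: Geometry) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = geometry.pixel_mm
    return aff


def _sidecar(path: Path) -> Path:
    return path.parent / (path.name.split(".")[0] + ".yaml")


def save_image_series(series: DynamicImageSeries, path: str | Path, extra: dict | None = None):
    path = Path(path)
    data = np.abs(series.frames) if np.iscomplexobj(series.frames) else series.frames
    vol = np.transpose(data, (2, 1, 0))[:, :, None, :]  # (x, y, 1, t)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _nifti_affine(series.geometry)), path)
    meta = {
        "fps": float(series.fps),
        "fov_mm": float(series.geometry.fov_mm),
        "matrix": int(series.geometry.matrix),
        "intensity_table": series.intensity_table,
    }
    meta.update(extra or {})
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_image_series(path: str | Path) -> DynamicImageSeries:
    path = Path(path)
    vol = np.asarray(nib.load(path).dataobj)
    frames = np.transpose(vol[:, :, 0, :], (2, 1, 0)).astype(float)
    meta = yaml.safe_load(_sidecar(path).read_text())
    return DynamicImageSeries(
        frames=frames,
        fps=meta["fps"],
        geometry=Geometry(matrix=meta["matrix"], fov_mm=meta["fov_mm"]),
        intensity_table=meta.get("intensity_table"),
    )


def save_mask_series(masks: RegionMaskSeries, path: str | Path, extra: dict | None = None):
    """Store disjoint region masks as one label volume (1-based labels)."""
    path = Path(path)
    regions = masks.regions
    T = masks.n_frames
    N = masks.geometry.matrix
    labels = np.zeros((T, N, N), dtype=np.uint8)
    for i, r in enumerate(regions, start=1):
        overlap = (labels > 0) & masks.masks[r]
        if overlap.any():
            raise ValueError("masks overlap; resolve_overlaps before saving labels")
        labels[masks.masks[r]] = i
    vol = np.transpose(labels, (2, 1, 0))[:, :, None, :]
    nib.save(nib.Nifti1Image(vol, _nifti_affine(masks.geometry)), path)
    meta = {
        "fps": float(masks.fps),
        "fov_mm": float(masks.geometry.fov_mm),
        "matrix": int(masks.geometry.matrix),
        "regions": list(regions),
    }
    meta.update(extra or {})
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_mask_series(path: str | Path) -> RegionMaskSeries:
    path = Path(path)
    vol = np.asarray(nib.load(path).dataobj)
    labels = np.transpose(vol[:, :, 0, :], (2, 1, 0))
    meta = yaml.safe_load(_sidecar(path).read_text())
    masks = {
        r: labels == i for i, r in enumerate(meta["regions"], start=1)
    }
    return RegionMaskSeries(
        masks=masks,
        fps=meta["fps"],
        geometry=Geometry(matrix=meta["matrix"], fov_mm=meta["fov_mm"]),
    )


def save_kspace(kspace: KSpaceSeries, path: str | Path, extra: dict | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace_real", data=kspace.frames.real)
        f.create_dataset("kspace_imag", data=kspace.frames.imag)
        f.attrs["fps"] = kspace.fps
        f.attrs["fov_mm"] = kspace.geometry.fov_mm
        f.attrs["matrix"] = kspace.geometry.matrix
        f.attrs["convention"] = CONVENTION
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def load_kspace(path: str | Path) -> KSpaceSeries:
    with h5py.File(path, "r") as f:
        frames = f["kspace_real"][()] + 1j * f["kspace_imag"][()]
        return KSpaceSeries(
            frames=frames,
            fps=float(f.attrs["fps"]),
            geometry=Geometry(matrix=int(f.attrs["matrix"]), fov_mm=float(f.attrs["fov_mm"])),
        )


def save_acquisition(acq: MultiCoilKSpace, path: str | Path, traj: Trajectory | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("samples_real", data=acq.data.real)
        f.create_dataset("samples_imag", data=acq.data.imag)
        f.create_dataset("pattern", data=acq.pattern)
        if acq.acs_data is not None:
            f.create_dataset("acs_real", data=acq.acs_data.real)
            f.create_dataset("acs_imag", data=acq.acs_data.imag)
        if traj is not None:
            f.create_dataset("traj", data=traj.points)
            if traj.dcf is not None:
                f.create_dataset("dcf", data=traj.dcf)
            f.attrs["kind"] = traj.kind
        f.attrs.update({
            "R": acq.R, "acs_lines": acq.acs_lines, "fps": acq.fps,
            "fov_mm": acq.geometry.fov_mm, "matrix": acq.geometry.matrix,
            "noise_sigma": acq.noise_sigma, "seed": acq.seed,
            "convention": CONVENTION,
        })


def load_acquisition(path: str | Path) -> MultiCoilKSpace:
    with h5py.File(path, "r") as f:
        acs = None
        if "acs_real" in f:
            acs = f["acs_real"][()] + 1j * f["acs_imag"][()]
        return MultiCoilKSpace(
            data=f["samples_real"][()] + 1j * f["samples_imag"][()],
            pattern=f["pattern"][()],
            R=int(f.attrs["R"]),
            acs_lines=int(f.attrs["acs_lines"]),
            fps=float(f.attrs["fps"]),
            geometry=Geometry(matrix=int(f.attrs["matrix"]), fov_mm=float(f.attrs["fov_mm"])),
            acs_data=acs,
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=int(f.attrs["seed"]),
        )


def read_rois(path: str | Path) -> list[RoiSpec]:
    """ROI polygons from YAML: ``{region: [[r, c], ...], ...}``."""
    spec = yaml.safe_load(Path(path).read_text())
    return [RoiSpec(region_name=name, polygon=tuple(map(tuple, verts)))
            for name, verts in spec.items()]


def write_rois(rois: list[RoiSpec], path: str | Path):
    Path(path).write_text(yaml.safe_dump(
        {r.region_name: [list(v) for v in r.polygon] for r in rois}
    ))
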