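"""On-disk formats and geometry conventions.

Conventions (used everywhere in the package):

* voxel indices are 0-based; world coordinates are mm from the volume origin
  through the NIfTI affine, which for phantoms is ``diag(voxel_size, 1)`` so
  voxel ``(i, j, k)`` sits at ``(i*dx, j*dy, k*dz)`` mm;
* ROI centers and diameters are specified in mm;
* circular/spherical ROIs are rasterized by center-of-voxel inclusion: a voxel
  belongs to the ROI iff its center lies within the circle/sphere (closed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MultimodalVolumeSet",
    "RoiDefinition",
    "read_volume_set",
    "write_volume_set",
    "write_results",
    "rasterize_roi",
    "area_to_diameter",
]

ROI_LABELS = ("V", "VII", "XII", "control", "custom")


@dataclass
class MultimodalVolumeSet:
    """Aligned 3D volumes keyed by acquisition condition.

    All volumes must share shape; voxel size (mm) and axis orientation are
    recorded once for the set.
    """

    volumes: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("volume set is empty")
        shapes = {k: v.shape for k, v in self.volumes.items()}
        first = next(iter(shapes.values()))
        bad = {k: s for k, s in shapes.items() if s != first}
        if bad:
            raise ValueError(f"volume shapes differ from {first}: {bad}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive mm values, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    def __getitem__(self, key: str) -> np.ndarray:
        return self.volumes[key]

    def __contains__(self, key: str) -> bool:
        return key in self.volumes


@dataclass(frozen=True)
class RoiDefinition:
    """Circular (2D, on one slice) or spherical (3D) region of interest.

    ``control_link`` names the paired control region used for normalized
    contrast; nucleus ROIs must carry one, the control ROI itself does not.
    """

    label: str
    center: tuple[float, float, float]  # mm
    diameter: float  # mm
    slice_index: int | None = None  # axis-2 slice for 2D ROIs; None = 3D sphere
    control_link: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"roi label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.diameter <= 0:
            raise ValueError("roi diameter must be positive")


def area_to_diameter(area_mm2: float) -> float:
    """Diameter of the circle with the given area (mm^2 -> mm)."""
    return 2.0 * np.sqrt(area_mm2 / np.pi)


def rasterize_roi(
    roi: RoiDefinition,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    diameter_is_area: bool = False,
) -> np.ndarray:
    """Boolean voxel mask for an ROI by center-of-voxel inclusion.

    ``diameter_is_area=True`` reinterprets ``roi.diameter`` as an area in mm^2
    (the two readings of printed ROI sizes; both are supported explicitly).
    """
    d = area_to_diameter(roi.diameter) if diameter_is_area else roi.diameter
    r = d / 2.0
    center = np.asarray(roi.center, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    lo = np.maximum(np.floor((center - r) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center + r) / vs).astype(int) + 1, shape)
    if (lo >= hi).any():
        raise ValueError(f"ROI {roi.label!r} lies outside the volume bounds")
    mask = np.zeros(shape, dtype=bool)
    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1) * vs
    # closed disk with a relative epsilon so voxel centers sitting exactly on
    # the boundary are included regardless of float rounding direction
    r2 = r**2 * (1.0 + 1e-12)
    if roi.slice_index is None:
        inside = ((centers - center) ** 2).sum(axis=-1) <= r2
        mask[ii[inside], jj[inside], kk[inside]] = True
    else:
        if not 0 <= roi.slice_index < shape[2]:
            raise ValueError(f"slice_index {roi.slice_index} out of bounds for shape {shape}")
        inside = ((centers[..., :2] - center[:2]) ** 2).sum(axis=-1) <= r2
        in_slice = inside & (kk == roi.slice_index)
        mask[ii[in_slice], jj[in_slice], kk[in_slice]] = True
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} rasterizes to zero voxels")
    return mask


def write_volume_set(vs: MultimodalVolumeSet, out_dir: str | Path) -> dict[str, Path]:
    """One NIfTI-1 file per condition plus a JSON manifest; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for key, vol in vs.volumes.items():
        p = out_dir / f"{key}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), vs.affine), p)
        paths[key] = p
    manifest = {key: p.name for key, p in paths.items()}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"voxel_size": list(vs.voxel_size), "volumes": manifest}, fh, indent=2)
    return paths


def read_volume_set(
    paths: Mapping[str, str | Path] | None = None,
    manifest: str | Path | None = None,
) -> MultimodalVolumeSet:
    """Load a volume set from explicit ``{condition: path}`` or a manifest.

    All files must agree on shape and voxel size; mismatches raise.
    """
    if paths is None:
        if manifest is None:
            raise ValueError("provide either paths or a manifest")
        manifest = Path(manifest)
        with open(manifest) as fh:
            m = json.load(fh)
        if "volumes" not in m:
            raise ValueError(f"manifest {manifest} lacks a 'volumes' mapping")
        paths = {k: manifest.parent / v for k, v in m["volumes"].items()}
    volumes: dict[str, np.ndarray] = {}
    voxel_size: tuple[float, float, float] | None = None
    shape = None
    for key, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"volume for condition {key!r} not found: {p}")
        img = nib.load(p)
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = tuple(round(float(z), 9) for z in img.header.get_zooms()[:3])
        if shape is None:
            shape, voxel_size = data.shape, zooms
        elif data.shape != shape or zooms != voxel_size:
            raise ValueError(
                f"geometry mismatch for {key!r}: shape {data.shape} / voxel {zooms} "
                f"vs {shape} / {voxel_size}"
            )
        volumes[key] = data
    return MultimodalVolumeSet(volumes=volumes, voxel_size=voxel_size)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    maps: Mapping[str, "object"],
    out_dir: str | Path,
    metadata: Mapping | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write CSV tables, NIfTI parametric maps and run metadata JSON.

    ``maps`` values may be bare arrays or objects with ``.values`` (parametric
    maps).  Returns the file inventory.  Existing files raise unless
    ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, Path] = {}

    def _target(name: str) -> Path:
        p = out_dir / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
        return p

    for name, table in tables.items():
        p = _target(f"{name}.csv")
        table.to_csv(p, index=False)
        inventory[name] = p
    affine = np.diag(list(voxel_size) + [1.0])
    for name, m in maps.items():
        values = getattr(m, "values", m)
        p = _target(f"{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine), p)
        inventory[name] = p
    if metadata is not None:
        p = _target("run_metadata.json")
        with open(p, "w") as fh:
            json.dump(dict(metadata), fh, indent=2, default=str)
        inventory["run_metadata"] = p
    return inventory
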