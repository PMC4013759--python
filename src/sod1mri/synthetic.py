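"""Synthetic multimodal MRI phantoms, brightfield histology fields and cohorts.

Every generator emits a ground-truth object alongside its data so that each
downstream quantification stage (parametric maps, ROI contrast, hypointensity
detection, stain densitometry, group statistics) can be verified exactly on
noise-free input and statistically under noise.

The phantom geometry is deliberately schematic: the brainstem is an ellipsoid
and the three cranial motor nuclei (trigeminal V, facial VII, hypoglossal XII)
are spheres inside it.  What is emulated faithfully is the *signal model* of
each acquisition:

* T2-weighted: nucleus signal = brainstem signal x per-nucleus fold change
  (end-stage disease shows up to ~15-fold contrast, largest in nucleus VII).
* diffusion: mono-exponential decay ``S(b) = S0 exp(-b D_dir)`` per gradient
  direction, with region-wise ground-truth diffusivities.
* magnetization transfer: ``S_on = S_off (1 - MTR)``.
* gadolinium enhancement: ``S_post = S_pre (1 + E)``.
* T2*-weighted: focal hypointense clusters of known voxel count and depth
  (signal = depth x in-mask mean), mimicking bound iron-oxide microparticles.

Noise, when requested, is applied last: Gaussian, or Rician
``sqrt((S + n1)^2 + n2^2)`` as appropriate for magnitude-reconstructed MRI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusSpec",
    "ClusterSpec",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "EllipseSpec",
    "HistologySpec",
    "CohortDesign",
    "generate_mri_phantom",
    "generate_histology_image",
    "generate_cohort",
    "add_noise",
]

# region labels in the phantom label map
BACKGROUND = "background"
BRAINSTEM = "brainstem"
NUCLEUS_LABELS = ("V", "VII", "XII")

#: Ruifrok & Johnston H-DAB absorption unit vectors (rows: stain; cols: R,G,B).
HDAB_VECTORS = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.269, 0.568, 0.778],  # DAB
    ]
)
HDAB_VECTORS /= np.linalg.norm(HDAB_VECTORS, axis=1, keepdims=True)

# Hypointensity rule defaults used to pre-classify injected clusters.
DEFAULT_HYPO_FRACTION = 0.65
DEFAULT_SIZE_CUTOFF = 20


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, all lengths in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        d = (xyz - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d**2).sum(axis=-1) <= 1.0


@dataclass(frozen=True)
class NucleusSpec:
    """Spherical motor-nucleus ROI: label in {V, VII, XII}, mm geometry."""

    label: str
    center: tuple[float, float, float]
    diameter: float


@dataclass(frozen=True)
class ClusterSpec:
    """An injected T2* hypointense cluster.

    ``depth`` is the cluster signal expressed as a fraction of the in-mask
    mean, so detector threshold behaviour is directly controllable.
    """

    center: tuple[float, float, float]
    size: int
    depth: float


def _default_nuclei() -> tuple[NucleusSpec, ...]:
    return (
        NucleusSpec("V", center=(1.6, 3.2, 2.4), diameter=1.4),
        NucleusSpec("VII", center=(3.2, 1.8, 2.4), diameter=1.2),
        NucleusSpec("XII", center=(4.8, 3.2, 2.4), diameter=1.1),
    )


@dataclass
class PhantomSpec:
    """Full description of a multimodal brainstem phantom.

    Defaults describe an end-stage disease brainstem: strong T2 hyperintensity
    (largest in the facial nucleus VII), reduced diffusivity and reduced MTR in
    the nuclei, and no gadolinium enhancement anywhere (no blood-brain-barrier
    leakage).
    """

    grid_shape: tuple[int, int, int] = (64, 48, 48)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    brainstem: Ellipsoid = field(
        default_factory=lambda: Ellipsoid(center=(3.2, 2.4, 2.4), semi_axes=(3.0, 2.0, 2.0))
    )
    nuclei: tuple[NucleusSpec, ...] = field(default_factory=_default_nuclei)
    #: multiplicative T2 contrast of each nucleus vs surrounding brainstem
    t2_fold_change: Mapping[str, float] = field(
        default_factory=lambda: {"V": 8.0, "VII": 15.0, "XII": 5.0}
    )
    #: per-region per-direction diffusivity, mm^2/s (x, y, z gradient axes)
    adc_truth: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            BRAINSTEM: (0.70e-3, 0.70e-3, 0.70e-3),
            "V": (0.55e-3, 0.55e-3, 0.55e-3),
            "VII": (0.50e-3, 0.50e-3, 0.50e-3),
            "XII": (0.55e-3, 0.55e-3, 0.55e-3),
        }
    )
    #: per-region magnetization transfer ratio, fraction of signal removed
    mtr_truth: Mapping[str, float] = field(
        default_factory=lambda: {BRAINSTEM: 0.35, "V": 0.28, "VII": 0.25, "XII": 0.28}
    )
    #: per-region fractional gadolinium enhancement (0 = intact barrier)
    enhancement_truth: Mapping[str, float] = field(
        default_factory=lambda: {BRAINSTEM: 0.0, "V": 0.0, "VII": 0.0, "XII": 0.0}
    )
    mpio_clusters: tuple[ClusterSpec, ...] = ()
    b_values: tuple[float, ...] = (125.0, 500.0, 1000.0)
    base_signal: float = 1000.0
    noise_model: str = "none"  # none | gaussian | rician
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.base_signal <= 0:
            raise ValueError("base_signal must be positive")
        if len(self.b_values) < 2:
            raise ValueError("need at least two b-values")
        for nuc in self.nuclei:
            if nuc.label not in NUCLEUS_LABELS:
                raise ValueError(f"unknown nucleus label {nuc.label!r}")
            if nuc.diameter <= 0:
                raise ValueError(f"nucleus {nuc.label}: diameter must be positive")
            # nucleus must lie inside the brainstem mask (check extreme points)
            c = np.asarray(nuc.center)
            r = nuc.diameter / 2.0
            extremes = c + r * np.concatenate([np.eye(3), -np.eye(3)])
            if not self.brainstem.contains(extremes).all():
                raise ValueError(f"nucleus {nuc.label} is not inside the brainstem mask")
        for region, fold in self.t2_fold_change.items():
            if fold < 1.0:
                raise ValueError(f"t2_fold_change[{region!r}] must be >= 1 for disease regions")
        for region, d in self.adc_truth.items():
            if not all(0.0 < di < 4e-3 for di in np.atleast_1d(d)):
                raise ValueError(f"adc_truth[{region!r}] must lie in (0, 4e-3) mm^2/s")
        for region, m in self.mtr_truth.items():
            if not 0.0 <= m < 1.0:
                raise ValueError(f"mtr_truth[{region!r}] must lie in [0, 1)")
        for cl in self.mpio_clusters:
            if cl.size <= 0:
                raise ValueError("cluster size must be positive")
            if not 0.0 <= cl.depth:
                raise ValueError("cluster depth must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth emitted with every synthetic dataset.

    MRI phantoms fill ``label_map`` and the per-region tables; histology
    images fill the density fields and vacuole mask; cohorts fill ``design``.
    """

    label_map: np.ndarray | None = None
    region_names: tuple[str, ...] = ()
    t2_contrast: dict[str, float] = field(default_factory=dict)
    adc: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    mtr: dict[str, float] = field(default_factory=dict)
    enhancement: dict[str, float] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    # histology
    dab_density: np.ndarray | None = None
    hematoxylin_density: np.ndarray | None = None
    vacuole_mask: np.ndarray | None = None
    stain_vectors: np.ndarray | None = None
    i0: np.ndarray | None = None
    # cohort
    design: dict | None = None

    def region_mask(self, region: str) -> np.ndarray:
        idx = self.region_names.index(region)
        return self.label_map == idx

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map > 0


def _voxel_centers_mm(grid_shape, voxel_size) -> np.ndarray:
    """World coordinates (mm) of voxel centers, index i -> i * voxel_size."""
    axes = [np.arange(n) * v for n, v in zip(grid_shape, voxel_size)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _build_label_map(spec: PhantomSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    xyz = _voxel_centers_mm(spec.grid_shape, spec.voxel_size)
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    labels[spec.brainstem.contains(xyz)] = 1
    names = [BACKGROUND, BRAINSTEM]
    for nuc in spec.nuclei:
        r = nuc.diameter / 2.0
        # closed ball with the same relative epsilon as ROI rasterization, so
        # nucleus masks and rasterized ROIs agree on boundary voxel centers
        inside = ((xyz - np.asarray(nuc.center)) ** 2).sum(axis=-1) <= r**2 * (1.0 + 1e-12)
        labels[inside] = len(names)
        names.append(nuc.label)
    return labels, tuple(names)


def _region_value_map(labels, names, table, default):
    """Per-voxel array from a region -> value mapping (vector values allowed)."""
    sample = np.atleast_1d(np.asarray(default, dtype=float))
    out = np.zeros(labels.shape + sample.shape, dtype=float)
    out[...] = sample
    for region, value in table.items():
        if region not in names:
            continue
        out[labels == names.index(region)] = np.atleast_1d(np.asarray(value, dtype=float))
    return out


def _cluster_voxels(center_mm, size, spec, mask):
    """The ``size`` in-mask voxels nearest ``center_mm`` (a digital ball)."""
    center_vox = np.asarray(center_mm) / np.asarray(spec.voxel_size)
    idx = np.argwhere(mask)
    d2 = ((idx - center_vox) ** 2).sum(axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    if size > len(idx):
        raise ValueError(
            f"cluster of {size} voxels at {center_mm} exceeds tissue mask ({len(idx)} voxels)"
        )
    chosen = idx[order[:size]]
    # reject clusters that had to skip outside the mask (non-compact growth):
    # the ball radius of the chosen set must not exceed the in-mask reach
    r_max = np.sqrt(d2[order[size - 1]])
    ball = ((_voxel_centers_mm(spec.grid_shape, spec.voxel_size) / spec.voxel_size - center_vox) ** 2).sum(axis=-1) <= r_max**2
    if (ball & ~mask).sum() > 0:
        raise ValueError(
            f"cluster of {size} voxels at {center_mm} exceeds the tissue mask boundary"
        )
    return chosen


def add_noise(volume: np.ndarray, model: str, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Gaussian or Rician (magnitude) noise; ``none`` returns a copy."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if model == "none" or sigma == 0.0:
        return volume.copy()
    if model == "gaussian":
        return volume + rng.normal(0.0, sigma, volume.shape)
    if model == "rician":
        n1 = rng.normal(0.0, sigma, volume.shape)
        n2 = rng.normal(0.0, sigma, volume.shape)
        return np.sqrt((volume + n1) ** 2 + n2**2)
    raise ValueError(f"unknown noise model {model!r}")


def generate_mri_phantom(spec: PhantomSpec):
    """Generate the full multimodal volume set plus its ground truth.

    Returns ``(MultimodalVolumeSet, PhantomTruth)``.  Condition keys:
    ``t2``, ``dwi_{x|y|z}_b{b}``, ``mt_off``, ``mt_on``, ``gd_pre``,
    ``gd_post``, ``t2star``.
    """
    from .io_formats import MultimodalVolumeSet

    spec.validate()
    labels, names = _build_label_map(spec)
    tissue = labels > 0
    base = spec.base_signal

    volumes: dict[str, np.ndarray] = {}

    # T2-weighted: per-nucleus fold change over brainstem signal
    fold = _region_value_map(labels, names, spec.t2_fold_change, default=1.0)[..., 0]
    t2 = np.where(tissue, base * fold, 0.0)
    volumes["t2"] = t2

    # diffusion: S(b) = S0 exp(-b D_dir), one volume per (direction, b)
    adc = _region_value_map(labels, names, spec.adc_truth, default=(0.7e-3,) * 3)
    for di, dname in enumerate("xyz"):
        for b in spec.b_values:
            s = np.where(tissue, base * np.exp(-b * adc[..., di]), 0.0)
            volumes[f"dwi_{dname}_b{int(b)}"] = s

    # magnetization transfer pair
    mtr = _region_value_map(labels, names, spec.mtr_truth, default=0.0)[..., 0]
    s_off = np.where(tissue, base, 0.0)
    volumes["mt_off"] = s_off
    volumes["mt_on"] = s_off * (1.0 - mtr)

    # gadolinium pair
    enh = _region_value_map(labels, names, spec.enhancement_truth, default=0.0)[..., 0]
    pre = np.where(tissue, base, 0.0)
    volumes["gd_pre"] = pre
    volumes["gd_post"] = pre * (1.0 + enh)

    # T2* with injected hypointense clusters
    t2star = np.where(tissue, base, 0.0)
    cluster_records = []
    taken = np.zeros(spec.grid_shape, dtype=bool)
    local_mean = t2star[tissue].mean()  # pre-injection mask mean (= base)
    for cl in spec.mpio_clusters:
        vox = _cluster_voxels(cl.center, cl.size, spec, tissue)
        ii = tuple(vox.T)
        if taken[ii].any():
            raise ValueError(f"cluster at {cl.center} overlaps a previously placed cluster")
        taken[ii] = True
        t2star[ii] = cl.depth * local_mean
        cluster_records.append(
            {
                "center_mm": tuple(cl.center),
                "centroid_voxel": tuple(vox.mean(axis=0)),
                "size": int(cl.size),
                "depth": float(cl.depth),
                "retained": bool(
                    cl.depth < DEFAULT_HYPO_FRACTION and cl.size <= DEFAULT_SIZE_CUTOFF
                ),
            }
        )
    volumes["t2star"] = t2star

    rng = np.random.default_rng(spec.seed)
    for key in list(volumes):
        volumes[key] = add_noise(volumes[key], spec.noise_model, spec.noise_sigma, rng)

    truth = PhantomTruth(
        label_map=labels,
        region_names=names,
        t2_contrast={n.label: spec.t2_fold_change.get(n.label, 1.0) - 1.0 for n in spec.nuclei},
        adc={r: tuple(np.atleast_1d(v)) for r, v in spec.adc_truth.items()},
        mtr=dict(spec.mtr_truth),
        enhancement=dict(spec.enhancement_truth),
        clusters=cluster_records,
    )
    vs = MultimodalVolumeSet(volumes=volumes, voxel_size=tuple(spec.voxel_size))
    return vs, truth


# ---------------------------------------------------------------------------
# brightfield histology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseSpec:
    """Vacuole: ellipse with center/axes in pixels and rotation in radians."""

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float = 0.0


@dataclass
class HistologySpec:
    """Beer-Lambert synthesis spec for an H-DAB stained brightfield field."""

    image_shape: tuple[int, int] = (256, 256)
    i0: tuple[float, float, float] = (255.0, 255.0, 255.0)
    stain_vectors: np.ndarray = field(default_factory=lambda: HDAB_VECTORS.copy())
    #: scalar or (H, W) array of DAB optical-density amounts
    dab_density: float | np.ndarray = 0.0
    hematoxylin_density: float | np.ndarray = 0.3
    vacuoles: tuple[EllipseSpec, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.i0):
            raise ValueError("i0 must be positive per channel")
        vecs = np.asarray(self.stain_vectors, dtype=float)
        if vecs.ndim != 2 or vecs.shape[1] != 3 or vecs.shape[0] not in (2, 3):
            raise ValueError("stain_vectors must be a (2,3) or (3,3) array")
        if (vecs < 0).any():
            raise ValueError("stain vectors must be non-negative")
        if not np.allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        if np.linalg.matrix_rank(vecs, tol=1e-8) < vecs.shape[0]:
            raise ValueError("stain vectors are collinear")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _ellipse_mask(shape, ell: EllipseSpec) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - ell.center[0]
    dc = cc - ell.center[1]
    ca, sa = np.cos(ell.angle), np.sin(ell.angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / ell.axes[0]) ** 2 + (v / ell.axes[1]) ** 2 <= 1.0


def generate_histology_image(spec: HistologySpec):
    """Synthesize an RGB brightfield image via Beer-Lambert absorption.

    ``I_c = I0_c * 10**(-sum_s density_s * stainvec_{s,c})``; vacuole pixels
    are rendered at background (white) intensity, i.e. zero stain density.
    Returns ``(image, PhantomTruth)`` with the image as float64 (H, W, 3).
    """
    spec.validate()
    h, w = spec.image_shape
    dab = np.broadcast_to(np.asarray(spec.dab_density, dtype=float), (h, w)).copy()
    hem = np.broadcast_to(np.asarray(spec.hematoxylin_density, dtype=float), (h, w)).copy()

    vac = np.zeros((h, w), dtype=bool)
    for ell in spec.vacuoles:
        vac |= _ellipse_mask((h, w), ell)
    dab[vac] = 0.0
    hem[vac] = 0.0

    vecs = np.asarray(spec.stain_vectors, dtype=float)
    densities = np.stack([hem, dab], axis=-1)  # (H, W, 2) in H, DAB order
    if vecs.shape[0] == 3:
        densities = np.concatenate([densities, np.zeros((h, w, 1))], axis=-1)
    od = densities @ vecs  # (H, W, 3)
    i0 = np.asarray(spec.i0, dtype=float)
    image = i0 * np.power(10.0, -od)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, i0)

    truth = PhantomTruth(
        dab_density=dab,
        hematoxylin_density=hem,
        vacuole_mask=vac,
        stain_vectors=vecs,
        i0=i0,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Per-cell sampling parameters for a cross-sectional two-group cohort.

    ``cells`` maps ``(group, age)`` to ``(mean, sd)`` of the Gaussian the
    per-animal ROI measurement is drawn from.  Groups default to the disease
    model vs wild-type littermates; ages to the five scan time points (days).
    """

    cells: Mapping[tuple[str, int], tuple[float, float]]
    region: str = "VII"
    modality: str = "t2"

    @classmethod
    def null(cls, groups=("SOD1", "WT"), ages=(40, 60, 80, 100, 120), mean=0.0, sd=1.0, **kw):
        return cls(cells={(g, a): (mean, sd) for g in groups for a in ages}, **kw)

    @classmethod
    def with_effect(
        cls, d: float, ages=(40, 60, 80, 100, 120), affected_ages=None, sd=1.0, **kw
    ):
        """Null design plus a standardized shift ``d`` in the disease group."""
        affected = set(ages if affected_ages is None else affected_ages)
        cells = {}
        for a in ages:
            cells[("WT", a)] = (0.0, sd)
            cells[("SOD1", a)] = (d * sd if a in affected else 0.0, sd)
        return cls(cells=cells, **kw)


def generate_cohort(design: CohortDesign, n_per_cell: int, seed: int):
    """Draw per-animal measurements; returns ``(DataFrame, PhantomTruth)``.

    Long format: columns animal, group, age, region, modality, value.
    """
    if n_per_cell < 2:
        raise ValueError("need n >= 2 animals per cell")
    for cell, (mu, sd) in design.cells.items():
        if sd <= 0:
            raise ValueError(f"cell {cell}: SD must be positive")
    rng = np.random.default_rng(seed)
    cells = list(design.cells.items())
    k = len(cells)
    draws = rng.normal(0.0, 1.0, (k, n_per_cell))
    groups = np.repeat([g for (g, _), _ in cells], n_per_cell)
    ages = np.repeat([a for (_, a), _ in cells], n_per_cell)
    mus = np.repeat([p[0] for _, p in cells], n_per_cell)
    sds = np.repeat([p[1] for _, p in cells], n_per_cell)
    table = pd.DataFrame(
        {
            "animal": np.arange(k * n_per_cell),
            "group": groups,
            "age": ages,
            "region": design.region,
            "modality": design.modality,
            "value": mus + sds * draws.ravel(),
        }
    )
    truth = PhantomTruth(
        design={
            "cells": {f"{g}:{a}": list(p) for (g, a), p in design.cells.items()},
            "n_per_cell": n_per_cell,
            "region": design.region,
            "modality": design.modality,
            "seed": seed,
        }
    )
    return table, truth
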