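"""DAB densitometry via colour deconvolution, and H&E vacuolation scoring.

Brightfield immunostaining obeys Beer-Lambert absorption, so pixel optical
densities ``OD_c = -log10(I_c / I0_c)`` are linear in the amounts of each
stain.  With known stain absorption vectors (rows of M), per-pixel densities
follow by solving ``OD = density @ M`` (Ruifrok-Johnston unmixing); a
two-stain system is completed with the normalized cross product so M is
square.  DAB immunoreactivity is then the mean DAB density inside a standard
circle, averaged over the sections through the nucleus.

Vacuolation on H&E: background-subtract, binarize (vacuoles are the bright
holes), and score an ROI as area x mean of the binary image — which equals
the vacuole pixel count inside the ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic import HDAB_VECTORS

__all__ = [
    "StainDensityMap",
    "VacuolationScore",
    "rgb_to_od",
    "color_deconvolve",
    "mean_dab_od",
    "score_vacuolation",
    "circle_mask",
    "polygon_mask",
]

#: relative clipping floor applied to intensities before the log
OD_CLIP_EPS = 1e-12
#: condition-number ceiling above which stain vectors count as collinear
MAX_CONDITION_NUMBER = 1e6


@dataclass
class StainDensityMap:
    """Per-stain density images (optical-density units) from unmixing."""

    densities: dict[str, np.ndarray]
    stain_vectors: np.ndarray  # the completed, square mixing matrix rows
    stain_names: tuple[str, ...]
    i0: np.ndarray | None = None
    n_negative_clipped: int = 0

    def __getitem__(self, stain: str) -> np.ndarray:
        return self.densities[stain]


@dataclass(frozen=True)
class VacuolationScore:
    roi_area: int  # pixels
    mean_binary: float  # fraction of ROI pixels inside vacuoles
    threshold: float
    method: str

    @property
    def total_vacuolation(self) -> float:
        """area x average vacuolation = vacuole pixel count in the ROI."""
        return self.roi_area * self.mean_binary


def rgb_to_od(image: np.ndarray, i0) -> np.ndarray:
    """Optical density per channel: OD = -log10(I / I0), clipped to I in
    [eps*I0, I0] so the result is finite and non-negative."""
    i0 = np.asarray(i0, dtype=float)
    if (i0 <= 0).any():
        raise ValueError("i0 must be positive per channel")
    image = np.asarray(image, dtype=float)
    clipped = np.clip(image, OD_CLIP_EPS * i0, i0)
    return -np.log10(clipped / i0)


def _complete_stain_matrix(vecs: np.ndarray) -> np.ndarray:
    vecs = np.asarray(vecs, dtype=float)
    if vecs.ndim != 2 or vecs.shape[1] != 3 or vecs.shape[0] not in (2, 3):
        raise ValueError("stain_vectors must be (2,3) or (3,3)")
    norms = np.linalg.norm(vecs, axis=1)
    if (norms == 0).any():
        raise ValueError("zero stain vector")
    vecs = vecs / norms[:, None]
    if vecs.shape[0] == 2:
        residual = np.cross(vecs[0], vecs[1])
        nr = np.linalg.norm(residual)
        if nr < 1e-12:
            raise ValueError("stain vectors are collinear")
        vecs = np.vstack([vecs, residual / nr])
    if np.linalg.cond(vecs) > MAX_CONDITION_NUMBER:
        raise ValueError("stain matrix is ill-conditioned (collinear vectors)")
    return vecs


def color_deconvolve(
    od_image: np.ndarray,
    stain_vectors: np.ndarray = HDAB_VECTORS,
    stain_names: Sequence[str] = ("hematoxylin", "dab"),
    i0: np.ndarray | None = None,
    clip_negative: bool = True,
) -> StainDensityMap:
    """Unmix an OD image into per-stain density maps.

    ``stain_vectors`` rows are unit absorption vectors (2 stains are completed
    with an orthogonal residual).  Negative densities — noise pushing a pixel
    outside the stain simplex — are clipped to 0 and counted.
    """
    od = np.asarray(od_image, dtype=float)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise ValueError("od_image must be (H, W, 3)")
    m = _complete_stain_matrix(stain_vectors)
    names = tuple(stain_names)
    if len(names) == 2:
        names = names + ("residual",)
    if len(names) != 3:
        raise ValueError("need 2 or 3 stain names")
    densities = od @ np.linalg.inv(m)  # solves density @ m = od per pixel
    n_neg = int((densities < 0).sum())
    if clip_negative:
        densities = np.maximum(densities, 0.0)
    return StainDensityMap(
        densities={name: densities[..., i] for i, name in enumerate(names)},
        stain_vectors=m,
        stain_names=names,
        i0=None if i0 is None else np.asarray(i0, dtype=float),
        n_negative_clipped=n_neg,
    )


def circle_mask(shape: tuple[int, int], center: tuple[float, float], diameter_px: float) -> np.ndarray:
    """Pixel mask of a closed disk by center-of-pixel inclusion."""
    r = diameter_px / 2.0
    if (
        center[0] - r < -0.5 or center[1] - r < -0.5
        or center[0] + r > shape[0] - 0.5 or center[1] + r > shape[1] - 0.5
    ):
        raise ValueError("circle extends outside the image")
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r**2


def polygon_mask(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon2mask

    return polygon2mask(shape, np.asarray(vertices, dtype=float))


def mean_dab_od(
    sections: Sequence[StainDensityMap | np.ndarray],
    center: tuple[float, float],
    diameter_px: float,
    stain: str = "dab",
) -> float:
    """Mean DAB optical density in a standard circle, averaged over sections.

    Each section contributes the mean density over the disk; the final value
    is the unweighted mean across sections (matching per-nucleus scoring over
    the three largest cross-sections).
    """
    if not sections:
        raise ValueError("need at least one section")
    means = []
    for sec in sections:
        dens = sec[stain] if isinstance(sec, StainDensityMap) else np.asarray(sec, dtype=float)
        mask = circle_mask(dens.shape, center, diameter_px)
        means.append(float(dens[mask].mean()))
    return float(np.mean(means))


def score_vacuolation(
    image: np.ndarray,
    roi_mask: np.ndarray,
    binarization: str | float = "otsu",
    rolling_ball_radius: float | None = None,
) -> VacuolationScore:
    """Score vacuolation inside an ROI: area x mean of the binarized image.

    ``image`` is grayscale or RGB (averaged); vacuoles are bright (white holes
    in stained tissue), so the binary image is ``intensity > threshold``.
    ``binarization`` is ``"otsu"`` or a fixed threshold.  Optional rolling-ball
    background subtraction precedes thresholding.  A constant image defeats
    Otsu; it falls back to a mid-range threshold with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != img.shape:
        raise ValueError("roi mask and image shapes differ")
    if not roi_mask.any():
        raise ValueError("empty ROI")

    if rolling_ball_radius is not None:
        from skimage import restoration

        img = img - restoration.rolling_ball(img, radius=rolling_ball_radius)

    if isinstance(binarization, str):
        if binarization != "otsu":
            raise ValueError(f"unknown binarization {binarization!r}")
        lo, hi = float(img.min()), float(img.max())
        if lo == hi:
            warnings.warn(
                "degenerate single-intensity image: Otsu undefined, "
                "falling back to mid-range fixed threshold",
                stacklevel=2,
            )
            threshold = lo  # nothing strictly above -> no vacuoles
            method = "fixed(fallback)"
        else:
            from skimage.filters import threshold_otsu

            threshold = float(threshold_otsu(img))
            method = "otsu"
    else:
        threshold = float(binarization)
        method = "fixed"

    binary = img > threshold
    mean_binary = float(binary[roi_mask].mean())
    return VacuolationScore(
        roi_area=int(roi_mask.sum()),
        mean_binary=mean_binary,
        threshold=threshold,
        method=method,
    )
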