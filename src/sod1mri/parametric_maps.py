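"""Voxelwise parametric maps (ADC trace, MTR, Gd enhancement) and scan geometry.

The ADC fit is ordinary least squares on (b, ln S) with intercept — exact for
mono-exponential decay and the standard estimator when no b=0 image exists.
The trace map is the unweighted mean of the three orthogonal directional
diffusivities.  Voxels whose fit is impossible (non-positive signal) or
implausible (negative diffusivity) are flagged invalid in the map mask and
counted, never silently clipped or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ParametricMap",
    "AcquisitionGeometry",
    "fit_adc",
    "compute_mtr",
    "compute_enhancement",
    "voxel_resolution",
    "scan_duration",
]


@dataclass
class ParametricMap:
    """A derived voxelwise map with units and a validity mask.

    ``mask`` marks voxels whose value is valid; ``n_invalid`` counts voxels
    that were inside the analysis mask but failed fitting/validity rules.
    """

    values: np.ndarray
    kind: str  # adc_trace | adc_dir | mtr | enhancement
    units: str  # mm^2/s | fraction
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)
    n_invalid: int = 0

    def masked(self) -> np.ndarray:
        """Values with invalid/outside voxels as NaN."""
        out = np.where(self.mask, self.values, np.nan)
        return out


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Printed sequence parameters needed for geometry/duration arithmetic."""

    fov: tuple[float, ...]  # mm per axis
    matrix: tuple[int, ...]  # acquired points per axis
    zerofill: tuple[int, ...] | None = None  # reconstructed points per axis
    tr: float = 1.0  # s
    n_phase_encodes: int = 1
    n_averages: int = 1
    b_values: tuple[float, ...] = ()
    n_directions: int = 0

    def __post_init__(self) -> None:
        zf = self.zerofill if self.zerofill is not None else self.matrix
        if len(self.fov) != len(self.matrix) or len(zf) != len(self.fov):
            raise ValueError("fov, matrix and zerofill must have equal length")
        if any(f <= 0 for f in self.fov) or any(m <= 0 for m in self.matrix):
            raise ValueError("fov and matrix entries must be positive")
        if any(z < m for z, m in zip(zf, self.matrix)):
            raise ValueError("zerofill must be >= matrix on every axis")
        if self.tr <= 0 or self.n_phase_encodes <= 0 or self.n_averages <= 0:
            raise ValueError("tr, n_phase_encodes and n_averages must be positive")


def voxel_resolution(geom: AcquisitionGeometry) -> tuple[float, ...]:
    """Reconstructed voxel size: fov / zero-filled matrix, per axis (mm).

    Zero-filling pads k-space before Fourier reconstruction, so the nominal
    resolution is set by the reconstructed grid, not the acquired one.
    """
    zf = geom.zerofill if geom.zerofill is not None else geom.matrix
    return tuple(f / z for f, z in zip(geom.fov, zf))


def scan_duration(geom: AcquisitionGeometry, n_repeats: int = 1) -> float:
    """Spin-echo acquisition time: TR x phase encodes x averages x repeats (s).

    ``n_repeats`` covers series repetition, e.g. one acquisition per b-value.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return geom.tr * geom.n_phase_encodes * geom.n_averages * n_repeats


def _lstsq_slope(b: np.ndarray, ln_s: np.ndarray) -> np.ndarray:
    """OLS slope of ln S against b along the first axis (vectorized)."""
    b = b.reshape((-1,) + (1,) * (ln_s.ndim - 1))
    b_bar = b.mean(axis=0)
    s_bar = ln_s.mean(axis=0)
    num = ((b - b_bar) * (ln_s - s_bar)).sum(axis=0)
    den = ((b - b_bar) ** 2).sum(axis=0)
    return num / den


def fit_adc(
    dwi: Mapping[str, np.ndarray] | np.ndarray,
    b_values: Sequence[float],
    mask: np.ndarray | None = None,
    clip_negative: bool = False,
) -> tuple[ParametricMap, dict[str, ParametricMap]]:
    """Fit per-direction ADC maps and their trace from diffusion volumes.

    Parameters
    ----------
    dwi
        Either ``{direction: (n_b, *spatial) array}`` or an array of shape
        ``(n_directions, n_b, *spatial)``.
    b_values
        Diffusion weightings in s/mm^2; at least two distinct values.
    mask
        Boolean analysis mask; defaults to all voxels.
    clip_negative
        If True, negative fitted diffusivities are clipped to 0 and stay
        valid; by default they are flagged invalid instead.

    Returns
    -------
    (trace map, {direction: directional map}).  Diffusivity ``D = -slope`` of
    the OLS line through ``(b, ln S)``; the trace is the arithmetic mean of
    the directional maps, valid only where every direction is valid.
    """
    if isinstance(dwi, Mapping):
        names = list(dwi)
        stack = np.stack([np.asarray(dwi[k], dtype=float) for k in names], axis=0)
    else:
        stack = np.asarray(dwi, dtype=float)
        names = [f"dir{i}" for i in range(stack.shape[0])]
    b = np.asarray(b_values, dtype=float)
    if len(np.unique(b)) < 2:
        raise ValueError("need at least two distinct b-values")
    if stack.shape[1] != len(b):
        raise ValueError(f"got {stack.shape[1]} b-volumes per direction for {len(b)} b-values")
    spatial = stack.shape[2:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape does not match volume shape")

    dir_maps: dict[str, ParametricMap] = {}
    d_stack = np.empty((len(names),) + spatial)
    valid_stack = np.empty((len(names),) + spatial, dtype=bool)
    for i, name in enumerate(names):
        s = stack[i]
        positive = (s > 0).all(axis=0)
        fittable = mask & positive
        with np.errstate(divide="ignore", invalid="ignore"):
            ln_s = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), np.nan)
        d = -_lstsq_slope(b, ln_s)
        d = np.where(fittable, d, np.nan)
        valid = fittable.copy()
        negative = valid & (d < 0)
        if clip_negative:
            d = np.where(negative, 0.0, d)
        else:
            valid &= ~negative
        d_stack[i] = d
        valid_stack[i] = valid
        dir_maps[name] = ParametricMap(
            values=d,
            kind="adc_dir",
            units="mm^2/s",
            mask=valid,
            provenance={"direction": name, "b_values": list(map(float, b))},
            n_invalid=int((mask & ~valid).sum()),
        )
    trace_valid = valid_stack.all(axis=0) & mask
    trace = np.where(trace_valid, d_stack.mean(axis=0), np.nan)
    trace_map = ParametricMap(
        values=trace,
        kind="adc_trace",
        units="mm^2/s",
        mask=trace_valid,
        provenance={"directions": names, "b_values": list(map(float, b))},
        n_invalid=int((mask & ~trace_valid).sum()),
    )
    return trace_map, dir_maps


def compute_mtr(
    s_off: np.ndarray, s_on: np.ndarray, mask: np.ndarray | None = None
) -> ParametricMap:
    """Magnetization transfer ratio: MTR = (S_off - S_on) / S_off, a fraction.

    Voxels with non-positive S_off inside the mask are invalidated and
    counted.
    """
    s_off = np.asarray(s_off, dtype=float)
    s_on = np.asarray(s_on, dtype=float)
    if s_off.shape != s_on.shape:
        raise ValueError("MT-off and MT-on volumes must share shape")
    if mask is None:
        mask = np.ones(s_off.shape, dtype=bool)
    valid = mask & (s_off > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = np.where(valid, (s_off - s_on) / s_off, np.nan)
    return ParametricMap(
        values=mtr,
        kind="mtr",
        units="fraction",
        mask=valid,
        provenance={"source": ("mt_off", "mt_on")},
        n_invalid=int((mask & ~valid).sum()),
    )


def compute_enhancement(
    pre: np.ndarray, post: np.ndarray, mask: np.ndarray | None = None
) -> ParametricMap:
    """Fractional gadolinium enhancement: E = (post - pre) / pre.

    The post-contrast image is subtracted from the pre-contrast image and
    expressed relative to the pre-contrast image; non-positive pre-contrast
    voxels are invalidated and counted.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post volumes must share shape")
    if mask is None:
        mask = np.ones(pre.shape, dtype=bool)
    valid = mask & (pre > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, (post - pre) / pre, np.nan)
    return ParametricMap(
        values=e,
        kind="enhancement",
        units="fraction",
        mask=valid,
        provenance={"source": ("gd_pre", "gd_post")},
        n_invalid=int((mask & ~valid).sum()),
    )
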