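"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops, flood fill, per-voxel normal equations.
They share no code with the package modules they verify.
"""

from __future__ import annotations

import itertools

import numpy as np

_OFFSETS = {
    6: [o for o in itertools.product((-1, 0, 1), repeat=3) if sum(abs(x) for x in o) == 1],
    18: [
        o
        for o in itertools.product((-1, 0, 1), repeat=3)
        if 1 <= sum(abs(x) for x in o) <= 2
    ],
    26: [o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)],
}


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D boolean array via explicit BFS."""
    offsets = _OFFSETS[connectivity]
    remaining = set(map(tuple, np.argwhere(binary)))
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(comp)
    return components


def hypointensity_percent_brute(volume, mask, fraction, size_cutoff, connectivity):
    """Direct application of the hypointensity rule via flood fill."""
    mean = volume[mask].mean()
    threshold = fraction * mean
    sub = mask & (volume < threshold)
    comps = flood_fill_components(sub, connectivity)
    retained = [c for c in comps if len(c) <= size_cutoff]
    n_ret = sum(len(c) for c in retained)
    return 100.0 * n_ret / mask.sum(), sorted(len(c) for c in comps)


def adc_fit_brute(dwi: np.ndarray, b_values) -> np.ndarray:
    """Per-voxel, per-direction D via explicit 2x2 normal equations."""
    b = np.asarray(b_values, dtype=float)
    n_dir = dwi.shape[0]
    spatial = dwi.shape[2:]
    out = np.full((n_dir,) + spatial, np.nan)
    n = len(b)
    for d in range(n_dir):
        for idx in np.ndindex(*spatial):
            s = dwi[(d, slice(None)) + idx]
            if (s <= 0).any():
                continue
            y = np.log(s)
            sb, sb2, sy, sby = b.sum(), (b**2).sum(), y.sum(), (b * y).sum()
            det = n * sb2 - sb**2
            slope = (n * sby - sb * sy) / det
            out[(d,) + idx] = -slope
    return out


def roi_contrast_brute(values, roi_center, roi_diameter, ctl_center, ctl_diameter, voxel_size):
    """Normalized contrast via an explicit voxel loop (closed-disk 3D ROIs)."""
    vs = np.asarray(voxel_size, dtype=float)
    sums = {"roi": [0.0, 0], "ctl": [0.0, 0]}
    for idx in np.ndindex(*values.shape):
        pos = np.asarray(idx) * vs
        if np.sum((pos - roi_center) ** 2) <= (roi_diameter / 2) ** 2:
            sums["roi"][0] += values[idx]
            sums["roi"][1] += 1
        if np.sum((pos - ctl_center) ** 2) <= (ctl_diameter / 2) ** 2:
            sums["ctl"][0] += values[idx]
            sums["ctl"][1] += 1
    mean_roi = sums["roi"][0] / sums["roi"][1]
    mean_ctl = sums["ctl"][0] / sums["ctl"][1]
    return (mean_roi - mean_ctl) / mean_ctl


def vacuole_pixel_count_brute(binary: np.ndarray, roi_mask: np.ndarray) -> int:
    """Count binary-positive pixels inside the ROI, one pixel at a time."""
    count = 0
    for idx in np.ndindex(*binary.shape):
        if roi_mask[idx] and binary[idx]:
            count += 1
    return count


def holm_brute(pvalues) -> np.ndarray:
    """Holm step-down by literal rule application."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 0.0
    for rank, i in enumerate(order):
        candidate = (m - rank) * p[i]
        running = max(running, candidate)
        adj[i] = min(1.0, running)
    return np.array(adj)
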