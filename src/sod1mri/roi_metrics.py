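"""ROI-normalized contrast and fold-change time courses.

The study's core image metric is the normalized contrast of a motor-nucleus
ROI against a paired control region placed within the brainstem but outside
the nuclei: ``(mean_ROI - mean_control) / mean_control``.  For modalities in
which disease lowers the signal (ADC, MTR) the sign is inverted so that time
courses across modalities are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import RoiDefinition, rasterize_roi
from .parametric_maps import ParametricMap

__all__ = ["RoiMeasurement", "measure_roi", "fold_change_series"]


@dataclass(frozen=True)
class RoiMeasurement:
    roi_label: str
    modality: str
    mean_roi: float
    mean_control: float
    contrast: float
    inverted: bool
    n_voxels_roi: int
    n_voxels_control: int
    n_invalid_roi: int = 0
    n_invalid_control: int = 0


def _resolve(map_or_image) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(map_or_image, ParametricMap):
        return map_or_image.values, map_or_image.mask
    return np.asarray(map_or_image, dtype=float), None


def measure_roi(
    map_or_image,
    roi: RoiDefinition,
    control: RoiDefinition,
    voxel_size: tuple[float, float, float],
    invert: bool = False,
    modality: str = "",
    diameter_is_area: bool = False,
) -> RoiMeasurement:
    """Normalized ROI contrast against the paired control region.

    Accepts a bare array or a ParametricMap; invalid voxels (map mask False)
    are excluded from both means and counted.  ``invert`` negates the
    contrast for modalities where pathology decreases signal.
    """
    values, valid = _resolve(map_or_image)
    roi_mask = rasterize_roi(roi, values.shape, voxel_size, diameter_is_area)
    ctl_mask = rasterize_roi(control, values.shape, voxel_size, diameter_is_area)
    if valid is None:
        valid = np.isfinite(values)
    roi_ok = roi_mask & valid
    ctl_ok = ctl_mask & valid
    if not roi_ok.any():
        raise ValueError(f"ROI {roi.label!r} contains no valid voxels")
    if not ctl_ok.any():
        raise ValueError(f"control ROI {control.label!r} contains no valid voxels")
    mean_roi = float(values[roi_ok].mean())
    mean_ctl = float(values[ctl_ok].mean())
    if mean_ctl == 0:
        raise ValueError("control region mean is zero; contrast undefined")
    contrast = (mean_roi - mean_ctl) / mean_ctl
    if invert:
        contrast = -contrast
    return RoiMeasurement(
        roi_label=roi.label,
        modality=modality,
        mean_roi=mean_roi,
        mean_control=mean_ctl,
        contrast=float(contrast),
        inverted=invert,
        n_voxels_roi=int(roi_ok.sum()),
        n_voxels_control=int(ctl_ok.sum()),
        n_invalid_roi=int((roi_mask & ~valid).sum()),
        n_invalid_control=int((ctl_mask & ~valid).sum()),
    )


def fold_change_series(
    measurements: pd.DataFrame,
    value_col: str = "value",
    reference: str = "wt_age_matched",
    baseline_age: int | None = None,
    group_col: str = "group",
    age_col: str = "age",
    disease_group: str = "SOD1",
    control_group: str = "WT",
) -> pd.DataFrame:
    """Fold change of per-cell means against a reference cell.

    ``reference`` selects the normalization: ``"wt_age_matched"`` divides each
    disease-group cell mean by the same-age control-group mean;
    ``"baseline_age"`` divides every cell by that group's mean at
    ``baseline_age``.  The choice is recorded in the output.
    """
    if reference not in ("wt_age_matched", "baseline_age"):
        raise ValueError(f"unknown reference {reference!r}")
    cells = (
        measurements.groupby([group_col, age_col])[value_col].mean().rename("mean").reset_index()
    )
    rows = []
    for _, row in cells.iterrows():
        if reference == "wt_age_matched":
            ref_sel = cells[
                (cells[group_col] == control_group) & (cells[age_col] == row[age_col])
            ]
        else:
            if baseline_age is None:
                raise ValueError("baseline_age reference requires baseline_age")
            ref_sel = cells[
                (cells[group_col] == row[group_col]) & (cells[age_col] == baseline_age)
            ]
        if ref_sel.empty:
            raise ValueError(f"empty reference cell for {dict(row)}")
        ref_mean = float(ref_sel["mean"].iloc[0])
        if ref_mean == 0:
            raise ValueError("reference cell mean is zero; fold change undefined")
        rows.append(
            {
                group_col: row[group_col],
                age_col: row[age_col],
                "mean": float(row["mean"]),
                "reference_mean": ref_mean,
                "fold": float(row["mean"]) / ref_mean,
                "reference": reference,
            }
        )
    return pd.DataFrame(rows)
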