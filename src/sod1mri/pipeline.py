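"""End-to-end orchestration: phantom -> maps -> ROI/detector/histology -> stats.

A single RunConfig drives every stage with one seed; outputs are plain files
under the configured directory plus a reproducibility manifest recording the
config hash, seed and package version.  Stage order is fixed by dependency:
``maps``, ``roi`` and ``mpio`` need ``phantom``; ``stats`` needs ``cohort``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, mpio_detection, parametric_maps, roi_metrics, stats, synthetic
from .histology_quant import circle_mask, color_deconvolve, mean_dab_od, rgb_to_od, score_vacuolation

__all__ = ["RunConfig", "run_pipeline", "phantom_spec_from_dict"]

logger = logging.getLogger("sod1mri")

ALL_STAGES = ("phantom", "maps", "roi", "mpio", "histology", "cohort", "stats")
STAGE_DEPS = {
    "maps": "phantom",
    "roi": "phantom",
    "mpio": "phantom",
    "stats": "cohort",
}

_CONFIG_KEYS = {
    "stages", "seed", "out_dir", "phantom", "hypointensity", "roi",
    "histology", "cohort", "overwrite",
}


def phantom_spec_from_dict(d: dict, seed: int) -> synthetic.PhantomSpec:
    """Build a PhantomSpec from a plain config mapping (strict keys)."""
    d = dict(d)
    clusters = tuple(
        synthetic.ClusterSpec(tuple(c["center"]), int(c["size"]), float(c["depth"]))
        for c in d.pop("mpio_clusters", [])
    )
    nuclei = d.pop("nuclei", None)
    kwargs = {}
    for key in (
        "grid_shape", "voxel_size", "t2_fold_change", "adc_truth", "mtr_truth",
        "enhancement_truth", "b_values", "base_signal", "noise_model", "noise_sigma",
    ):
        if key in d:
            val = d.pop(key)
            if key in ("grid_shape", "voxel_size", "b_values"):
                val = tuple(val)
            kwargs[key] = val
    if d:
        raise ValueError(f"unknown phantom config keys: {sorted(d)}")
    if nuclei is not None:
        kwargs["nuclei"] = tuple(
            synthetic.NucleusSpec(n["label"], tuple(n["center"]), float(n["diameter"]))
            for n in nuclei
        )
    return synthetic.PhantomSpec(mpio_clusters=clusters, seed=seed, **kwargs)


@dataclass
class RunConfig:
    """Strict-schema pipeline configuration; defaults are the study values."""

    out_dir: str = "sod1mri_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    phantom: dict = field(default_factory=lambda: {
        "mpio_clusters": [
            {"center": [2.4, 2.4, 2.4], "size": 8, "depth": 0.4},
            {"center": [4.0, 2.4, 2.4], "size": 30, "depth": 0.4},
        ],
    })
    hypointensity: dict = field(default_factory=lambda: {
        "fraction": 0.65, "size_cutoff": 20, "connectivity": 26,
    })
    roi: dict = field(default_factory=lambda: {
        "control_center": [3.2, 3.4, 2.4],
        "control_diameter": 1.0,
        "diameter_is_area": False,
    })
    histology: dict = field(default_factory=lambda: {
        "image_shape": [192, 192],
        "dab_blob_density": 0.8,
        "vacuole_axes": [12.0, 8.0],
        "circle_diameter_px": 120.0,
    })
    cohort: dict = field(default_factory=lambda: {
        "n_per_cell": 4,
        "effect_d": 2.0,
        "affected_ages": [80, 100, 120],
    })
    overwrite: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, val in d.items():
            if key == "stages":
                val = tuple(val)
            setattr(cfg, key, val)
        for stage in cfg.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "seed": self.seed, "stages": list(self.stages),
            "phantom": self.phantom, "hypointensity": self.hypointensity,
            "roi": self.roi, "histology": self.histology, "cohort": self.cohort,
        }


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns a run report.

    Writes parametric maps (NIfTI), per-stage CSV tables, and a manifest JSON
    tying every output to the config hash and seed.  Identical config + seed
    reproduce identical result files.
    """
    for stage in config.stages:
        dep = STAGE_DEPS.get(stage)
        if dep and dep not in config.stages:
            raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out_dir / "run.log")
    logger.addHandler(fh)

    report: dict = {"config_hash": _config_hash(config), "seed": config.seed, "stages": {}}
    tables: dict[str, pd.DataFrame] = {}
    maps_out: dict[str, object] = {}
    spec = truth = vs = None

    try:
        if "phantom" in config.stages:
            logger.info("stage phantom")
            spec = phantom_spec_from_dict(config.phantom, seed=config.seed)
            vs, truth = synthetic.generate_mri_phantom(spec)
            io_formats.write_volume_set(vs, out_dir / "phantom")
            report["stages"]["phantom"] = {
                "conditions": sorted(vs.volumes),
                "n_tissue_voxels": int(truth.tissue_mask.sum()),
            }

        trace = mtr = enh = None
        if "maps" in config.stages:
            logger.info("stage maps")
            mask = truth.tissue_mask
            dwi = {
                d: np.stack([vs[f"dwi_{d}_b{int(b)}"] for b in spec.b_values])
                for d in "xyz"
            }
            trace, _ = parametric_maps.fit_adc(dwi, spec.b_values, mask)
            mtr = parametric_maps.compute_mtr(vs["mt_off"], vs["mt_on"], mask)
            enh = parametric_maps.compute_enhancement(vs["gd_pre"], vs["gd_post"], mask)
            maps_out.update({"adc_trace": trace, "mtr": mtr, "enhancement": enh})
            report["stages"]["maps"] = {
                k: {"n_invalid": m.n_invalid} for k, m in maps_out.items()
            }

        if "roi" in config.stages:
            logger.info("stage roi")
            control = io_formats.RoiDefinition(
                "control",
                tuple(config.roi["control_center"]),
                float(config.roi["control_diameter"]),
            )
            diameter_is_area = bool(config.roi.get("diameter_is_area", False))
            rows = []
            # contrast is measured on weighted images and derived maps whose
            # control region has signal; the enhancement map (zero under an
            # intact barrier) is summarized as a region mean instead
            images = {"t2": (vs["t2"], False), "t1_gd_post": (vs["gd_post"], False)}
            if trace is not None:
                images["adc_trace"] = (trace, True)
                images["mtr"] = (mtr, True)
            for nuc in spec.nuclei:
                roi = io_formats.RoiDefinition(
                    nuc.label, nuc.center, nuc.diameter, control_link="control"
                )
                for modality, (img, invert) in images.items():
                    m = roi_metrics.measure_roi(
                        img, roi, control, spec.voxel_size,
                        invert=invert, modality=modality,
                        diameter_is_area=diameter_is_area,
                    )
                    rows.append(vars(m))
            tables["roi_measurements"] = pd.DataFrame(rows)
            report["stages"]["roi"] = {"n_measurements": len(rows)}

        if "mpio" in config.stages:
            logger.info("stage mpio")
            res = mpio_detection.detect_hypointensities(
                vs["t2star"], truth.tissue_mask, **config.hypointensity
            )
            tables["hypointensities"] = pd.DataFrame(
                [
                    {
                        "threshold": res.threshold_value,
                        "n_clusters_retained": len(res.clusters_retained),
                        "n_clusters_excluded": len(res.clusters_excluded),
                        "n_hypo_voxels_retained": res.n_hypo_voxels_retained,
                        "n_mask_voxels": res.n_mask_voxels,
                        "percent_hypointense": res.percent_hypointense,
                    }
                ]
            )
            report["stages"]["mpio"] = {
                "percent_hypointense": res.percent_hypointense,
                "n_clusters_retained": len(res.clusters_retained),
            }

        if "histology" in config.stages:
            logger.info("stage histology")
            h = config.histology
            shape = tuple(h["image_shape"])
            rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
            c0 = (shape[0] / 2.0, shape[1] / 2.0)
            blob = (
                ((rr - c0[0]) ** 2 + (cc - c0[1]) ** 2)
                <= (min(shape) / 4.0) ** 2
            )
            hspec = synthetic.HistologySpec(
                image_shape=shape,
                dab_density=np.where(blob, float(h["dab_blob_density"]), 0.0),
                vacuoles=(
                    synthetic.EllipseSpec(
                        center=(shape[0] * 0.75, shape[1] * 0.25),
                        axes=tuple(h["vacuole_axes"]),
                    ),
                ),
                seed=config.seed,
            )
            image, h_truth = synthetic.generate_histology_image(hspec)
            od = rgb_to_od(image, hspec.i0)
            dens = color_deconvolve(od, hspec.stain_vectors)
            dab = mean_dab_od([dens], c0, float(h["circle_diameter_px"]))
            roi_mask = circle_mask(
                shape, (shape[0] * 0.75, shape[1] * 0.25), min(shape) * 0.45
            )
            vac = score_vacuolation(image, roi_mask, binarization="otsu")
            tables["histology_scores"] = pd.DataFrame(
                [
                    {
                        "mean_dab_od": dab,
                        "vacuolation_mean_binary": vac.mean_binary,
                        "total_vacuolation": vac.total_vacuolation,
                        "true_vacuole_pixels_in_roi": int(h_truth.vacuole_mask[roi_mask].sum()),
                    }
                ]
            )
            report["stages"]["histology"] = {"mean_dab_od": dab}

        cohort = None
        if "cohort" in config.stages:
            logger.info("stage cohort")
            c = config.cohort
            design = synthetic.CohortDesign.with_effect(
                d=float(c["effect_d"]), affected_ages=tuple(c["affected_ages"])
            )
            cohort, _ = synthetic.generate_cohort(design, int(c["n_per_cell"]), config.seed)
            tables["cohort"] = cohort
            report["stages"]["cohort"] = {"n_rows": len(cohort)}

        if "stats" in config.stages:
            logger.info("stage stats")
            ages = sorted(cohort["age"].unique())
            comparisons = [
                ({"group": "SOD1", "age": a}, {"group": "WT", "age": a}) for a in ages
            ]
            anova_table, posthoc = stats.anova_with_posthoc(cohort, comparisons)
            folds = roi_metrics.fold_change_series(cohort)
            tables["anova"] = anova_table
            tables["posthoc"] = posthoc
            tables["fold_change"] = folds
            report["stages"]["stats"] = {
                "n_significant": int((posthoc["p_holm"] < 0.05).sum()),
            }

        voxel_size = spec.voxel_size if spec is not None else (1.0, 1.0, 1.0)
        inventory = io_formats.write_results(
            tables, maps_out, out_dir / "results",
            metadata={
                "config": config.to_dict(),
                "config_hash": report["config_hash"],
                "seed": config.seed,
            },
            voxel_size=voxel_size,
            overwrite=config.overwrite,
        )
        report["outputs"] = {k: str(v) for k, v in inventory.items()}
        with open(out_dir / "manifest.json", "w") as f:
            json.dump(report, f, indent=2, default=str)
    finally:
        logger.removeHandler(fh)
        fh.close()
    return report
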