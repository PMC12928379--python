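"""End-to-end orchestration: overlays -> subtraction -> overlap -> disconnection.

``run_pipeline`` drives the full analysis from files on disk to files on
disk: cohort overlays (counts and proportions), the common lesion of cohort A
at a proportion threshold (default 0.80), the A-minus-B subtraction map
binarized at the max-difference threshold (or an explicit one), and — for
each of the two analysis maps — a parcel-overlap table against the atlas and
a tract-disconnection table against the streamline atlas.  A JSON run report
records every parameter, derived threshold, map maximum and product checksum;
timestamps are deliberately excluded so identical runs produce identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import yaml

from . import atlas_overlap, disconnection, overlay, subtraction, volumes
from .errors import LesionMapError, ParameterError

log = logging.getLogger("lesionmap")


class PipelineStageError(LesionMapError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``subtraction_tau`` is either the string ``"auto"`` (max-difference rule:
    max(A) - max(B)) or an explicit fraction in [-1, 1].  ``cohort_b_dir``
    may be None, in which case the subtraction branch is skipped and only the
    cohort-A products are built.  Atlas and tract paths are optional; their
    quantifier stages are skipped when absent.
    """

    cohort_a_dir: str
    out_dir: str
    cohort_b_dir: str | None = None
    common_lesion_tau: float = 0.80
    subtraction_tau: float | str = "auto"
    atlas_path: str | None = None
    atlas_lut: str | None = None
    tracts_dir: str | None = None
    cohort_a_name: str = "cohort_a"
    cohort_b_name: str = "cohort_b"
    binarize_threshold: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.common_lesion_tau <= 1.0:
            raise ParameterError("common_lesion_tau must lie in [0, 1]")
        if self.subtraction_tau != "auto" and not -1.0 <= float(self.subtraction_tau) <= 1.0:
            raise ParameterError("subtraction_tau must be 'auto' or in [-1, 1]")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Load a config from YAML or JSON (keyed by the field names)."""
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)  # YAML is a JSON superset
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the run report (also written to disk).

    On a stage failure the report is still written, with the failed stage
    recorded under ``"failed_stage"``, and a :class:`PipelineStageError` is
    raised; products written before the failure are retained.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "products": {},
        "thresholds": {},
        "map_maxima": {},
        "status": "RUNNING",
    }
    stage = "setup"

    def product(name: str, path: str) -> None:
        report["products"][name] = {
            "path": os.path.relpath(path, cfg.out_dir),
            "sha256": _sha256(path),
        }

    def out(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    try:
        stage = "load_cohort_a"
        cohort_a = volumes.load_cohort(cfg.cohort_a_dir, cfg.binarize_threshold)
        grid = volumes.check_cohort_grids(cohort_a)
        log.info("cohort A (%s): %d subjects", cfg.cohort_a_name, len(cohort_a))

        stage = "overlay_a"
        counts_a = overlay.count_overlay(cohort_a)
        pm_a = overlay.proportion_map(cohort_a, cfg.cohort_a_name)
        volumes.save_volume(counts_a.counts.astype("int16"), grid,
                            out("cohort_a_counts.nii.gz"))
        volumes.save_volume(pm_a.values.astype("float32"), grid,
                            out("cohort_a_proportion.nii.gz"))
        product("cohort_a_counts", out("cohort_a_counts.nii.gz"))
        product("cohort_a_proportion", out("cohort_a_proportion.nii.gz"))
        report["map_maxima"]["cohort_a_max_proportion"] = pm_a.max_proportion

        stage = "common_lesion"
        common = overlay.threshold_map(pm_a, cfg.common_lesion_tau)
        volumes.save_mask(common, out("common_lesion.nii.gz"))
        product("common_lesion", out("common_lesion.nii.gz"))
        report["thresholds"]["common_lesion_tau"] = cfg.common_lesion_tau
        report["common_lesion_voxels"] = common.n_lesioned
        analysis_maps = {"common_lesion": common}

        if cfg.cohort_b_dir is not None:
            stage = "load_cohort_b"
            cohort_b = volumes.load_cohort(cfg.cohort_b_dir, cfg.binarize_threshold)
            log.info("cohort B (%s): %d subjects", cfg.cohort_b_name, len(cohort_b))

            stage = "overlay_b"
            counts_b = overlay.count_overlay(cohort_b)
            pm_b = overlay.proportion_map(cohort_b, cfg.cohort_b_name)
            volumes.save_volume(counts_b.counts.astype("int16"), grid,
                                out("cohort_b_counts.nii.gz"))
            volumes.save_volume(pm_b.values.astype("float32"), grid,
                                out("cohort_b_proportion.nii.gz"))
            product("cohort_b_counts", out("cohort_b_counts.nii.gz"))
            product("cohort_b_proportion", out("cohort_b_proportion.nii.gz"))
            report["map_maxima"]["cohort_b_max_proportion"] = pm_b.max_proportion

            stage = "subtraction"
            sm = subtraction.subtract(pm_a, pm_b)
            if cfg.subtraction_tau == "auto":
                tau = subtraction.max_diff_threshold(pm_a, pm_b)
            else:
                tau = float(cfg.subtraction_tau)
            sub_bin = subtraction.binarize(sm, tau)
            volumes.save_volume(sm.values.astype("float32"), grid,
                                out("subtraction_map.nii.gz"))
            volumes.save_mask(sub_bin, out("subtraction_binarized.nii.gz"))
            product("subtraction_map", out("subtraction_map.nii.gz"))
            product("subtraction_binarized", out("subtraction_binarized.nii.gz"))
            report["thresholds"]["subtraction_tau"] = tau
            report["thresholds"]["subtraction_tau_rule"] = (
                "max_difference" if cfg.subtraction_tau == "auto" else "explicit")
            report["map_maxima"]["subtraction_range"] = list(sm.value_range)
            report["subtraction_binarized_voxels"] = sub_bin.n_lesioned
            analysis_maps["subtraction_binarized"] = sub_bin
            log.info("subtraction threshold: %.4f (%s)", tau,
                     report["thresholds"]["subtraction_tau_rule"])

        if cfg.atlas_path is not None:
            stage = "parcel_overlap"
            parc = volumes.load_parcellation(cfg.atlas_path, cfg.atlas_lut)
            for name, map_ in analysis_maps.items():
                table = atlas_overlap.parcel_overlap(map_, parc)
                path = out(f"overlap_{name}.csv")
                atlas_overlap.write_overlap_table(table, path)
                product(f"overlap_{name}", path)

        if cfg.tracts_dir is not None:
            stage = "disconnection"
            atlas = disconnection.load_tract_atlas(cfg.tracts_dir)
            for name, map_ in analysis_maps.items():
                table = disconnection.disconnection_report(atlas, map_)
                path = out(f"disconnection_{name}.csv")
                disconnection.write_disconnection_table(table, path)
                product(f"disconnection_{name}", path)

        report["status"] = "OK"
    except Exception as exc:
        report["status"] = "FAILED"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _write_report(report, cfg.out_dir)
        raise PipelineStageError(stage, exc) from exc

    _write_report(report, cfg.out_dir)
    return report


def _write_report(report: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
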