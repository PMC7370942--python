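"""End-to-end pipeline: point cloud -> labelled fiducials -> head-to-MNI
transform -> interpolated channel positions.

Each stage logs its inputs, parameters, counts and residuals; artifacts
(labelled fiducial CSV, channel CSV) land in the configured output
directory.  Stage failures propagate as PipelineStageError with the stage
name and a remediation hint.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .errors import CapRegError, PipelineStageError
from .io import (
    PipelineConfig,
    default_reference_mni_path,
    read_fiducials_csv,
    read_model_cap_table,
    read_point_cloud,
    write_channels_csv,
    write_fiducials_csv,
)
from .recovery import extract_fiducial_clusters, label_fiducials
from .registration import (
    fit_head_transform,
    project_channels,
    register_model_cap,
)
from .types import SessionMeasurement

__all__ = ["run_pipeline"]

_HINTS = {
    "load": "check the point-cloud and model-cap paths and formats",
    "register-model": "the model cap table must contain all 9 fiducials "
                      "and at least one probe",
    "extract": "check sticker hue/tolerance and the linkage radius",
    "label": "fewer than 5 sticker clusters were found; re-check hue "
             "settings or recording coverage",
    "fit-transform": "the labelled set must contain Nz, AL, AR and Cz",
    "project": "at least 5 of the model fiducials must be recovered",
}


def _stage(logger, name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CapRegError):
                logger.error("stage %s: failed (%s)", name, exc)
                raise PipelineStageError(name, exc,
                                         _HINTS.get(name, "")) from exc
            if exc is None:
                logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig,
                 logger: logging.Logger | None = None) -> SessionMeasurement:
    """Run extract -> label -> fit -> project per the configuration and
    return the per-channel MNI positions."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if logger is None:
        logger = logging.getLogger("capreg.pipeline")
        if not logger.handlers:
            handler = logging.FileHandler(out_dir / "pipeline.log",
                                          encoding="utf-8")
            handler.setFormatter(logging.Formatter(
                "%(asctime)s %(levelname)s %(message)s"))
            logger.addHandler(handler)
            logger.setLevel(logging.INFO)
    logger.info("pipeline start: config hash %s, seed %d",
                config.hash(), config.seed)

    with _stage(logger, "load"):
        cloud = read_point_cloud(config.point_cloud_path)
        fiducials, probes = read_model_cap_table(config.model_cap_path)
        ref_path = config.reference_mni_path or default_reference_mni_path()
        reference = read_fiducials_csv(ref_path)
        logger.info("loaded cloud with %d vertices, model with %d probes",
                    len(cloud), len(probes))

    with _stage(logger, "register-model"):
        model = register_model_cap(fiducials, probes)
        logger.info("model cap registered: %d weight rows, max |row sum - 1| "
                    "= %.2e", len(model.probe_ids),
                    abs(model.weights.sum(axis=1) - 1).max())

    with _stage(logger, "extract"):
        centroids = extract_fiducial_clusters(
            cloud, sticker_hue=config.sticker_hue, hue_tol=config.hue_tol,
            link_radius_mm=config.link_radius_mm,
            min_cluster_size=config.min_cluster_size)
        logger.info("extracted %d sticker clusters", len(centroids))

    with _stage(logger, "label"):
        labeling = label_fiducials(centroids, model.fiducials,
                                   seed=config.seed)
        logger.info("labeling cost %.3f mm over %d points",
                    labeling.fit_cost_mm, labeling.n_points_used)
        write_fiducials_csv(labeling.fiducials,
                            out_dir / "labeled_fiducials.csv",
                            cost=labeling.fit_cost_mm)

    with _stage(logger, "fit-transform"):
        head_transform = fit_head_transform(
            labeling.fiducials, reference,
            free_vertical=config.free_vertical_scale)
        logger.info("head transform residual %.3f mm, scales ap=%.4f "
                    "lr=%.4f vert=%.4f", head_transform.residual_mm,
                    head_transform.scale_ap, head_transform.scale_lr,
                    head_transform.scale_vert)

    with _stage(logger, "project"):
        measurement = project_channels(model, labeling.fiducials,
                                       head_transform)
        write_channels_csv(measurement.channel_positions,
                           out_dir / "channels_mni.csv")
        logger.info("projected %d channels",
                    len(measurement.channel_positions))

    logger.info("pipeline done")
    return measurement
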