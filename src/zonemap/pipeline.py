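"""End-to-end orchestration: select cells, run the zonation analysis,
contrast conditions.

These functions compose the module operations with structured logging of
every filter's accounting (veins found, ROI size, samples/proteins excluded
and why), so downstream "n =" numbers always reconcile.  They operate on
in-memory objects; the command-line layer handles file I/O around them.
"""

from __future__ import annotations

import logging

import numpy as np

from . import binned, gradient, qc, tissue
from .config import PipelineConfig
from .io import spatial_table
from .lmdxml import export_lmd_xml
from .qc import IntensityMatrix
from .tissue import CellContour, SpatialCell

logger = logging.getLogger("zonemap")

__all__ = ["run_select", "run_zonation", "run_contrast"]


def run_select(
    channels: dict[str, np.ndarray] | None,
    contours: list[CellContour],
    config: PipelineConfig,
    patient_id: str = "",
    reference_points: list[tuple[float, float]] | None = None,
) -> dict:
    """Detect veins (or use manual anchors), build the ROI, select cells.

    Returns the trajectory, the selected :class:`SpatialCell` list, the
    spatial table (selection order preserved) and the LMD XML text.
    """
    config.validate()
    if config.mode == "manual":
        traj = tissue.manual_trajectory(
            config.anchor_a, config.anchor_b, contours, config.cone_half_angle
        )
        logger.info("manual trajectory: anchors %s -> %s", config.anchor_a, config.anchor_b)
    else:
        if channels is None:
            raise ValueError("auto mode requires image channels")
        veins = tissue.detect_veins(
            channels["boundary"], config.min_vein_area,
            config.blur_sigma, config.dilation_radius,
        )
        logger.info("detected %d candidate veins", len(veins))
        veins = tissue.classify_veins(
            veins, channels["pericentral"], channels["periportal"], config.annulus_width
        )
        pairs = tissue.pair_trajectories(veins)
        if not pairs:
            raise ValueError("no central/portal vein pair found; use manual mode")
        traj = tissue.build_trajectory_roi(pairs[0], contours, config.cone_half_angle)
    logger.info("trajectory ROI holds %d cells", len(traj.roi_cells))

    selected = tissue.select_cells_fft(traj.roi_cells, config.k)
    cells = []
    for c in selected:
        d_c, d_p, S = tissue.compute_spatial_ratio(
            c.centroid, traj.central.anchor, traj.portal.anchor, config.orientation
        )
        cells.append(SpatialCell(contour=c, d_central=d_c, d_portal=d_p,
                                 S=S, patient_id=patient_id))
    logger.info("selected %d cells by farthest-first traversal", len(cells))

    if reference_points is None:
        reference_points = [traj.central.anchor, traj.portal.anchor,
                            (traj.central.anchor[0], traj.portal.anchor[1])]
    xml_text = export_lmd_xml([sc.contour for sc in cells], reference_points)
    return {
        "trajectory": traj,
        "cells": cells,
        "table": spatial_table(cells),
        "lmd_xml": xml_text,
    }


def run_zonation(matrix: IntensityMatrix, config: PipelineConfig) -> dict:
    """QC filters, continuous gradient fits, binned comparator, comparison."""
    config.validate()
    if matrix.values.size == 0:
        raise ValueError("empty intensity matrix")
    filtered, report = qc.filter_samples_by_id_count(matrix)
    for sid, reason in report.excluded.items():
        logger.info("sample %s excluded (%s ID count)", sid, reason)
    filtered = qc.filter_protein_completeness(filtered, config.min_completeness)
    logger.info(
        "after QC: %d proteins x %d samples",
        filtered.values.shape[0], filtered.values.shape[1],
    )
    if filtered.values.shape[0] == 0:
        raise ValueError("no protein passes the completeness filter")

    fits = gradient.fit_gradients(filtered, preprocess=True, tukey_k=config.tukey_k)
    for pid, reason in fits.loc[~fits["converged"], "skip_reason"].items():
        logger.info("protein %s skipped (%s)", pid, reason)

    b = binned.bin_by_spatial_ratio(filtered, config.n_bins)
    bz = binned.zscore_bins(b)
    anova = binned.anova_all_proteins(filtered, config.n_bins)
    comparison = binned.method_comparison(fits["q"], anova["q"], config.q_threshold)
    return {
        "matrix": filtered,
        "sample_qc": report,
        "fits": fits,
        "binned": b,
        "binned_z": bz,
        "order": binned.order_by_gradient(bz),
        "anova": anova,
        "comparison": comparison,
    }


def run_contrast(
    matrix: IntensityMatrix,
    config: PipelineConfig,
    condition_a: str = "healthy",
    condition_b: str = "disease",
) -> dict:
    """Per-condition gradient fits, Delta_beta1 contrasts and the summary."""
    config.validate()
    cond = matrix.meta["condition"].astype(str)
    for label in (condition_a, condition_b):
        if not (cond == label).any():
            raise ValueError(f"condition {label!r} has no samples")

    results = {}
    for label in (condition_a, condition_b):
        sub = matrix.subset_samples(matrix.meta.index[cond == label])
        results[label] = run_zonation(sub, config)
    fits_a = results[condition_a]["fits"]
    fits_b = results[condition_b]["fits"]
    contrasts = gradient.contrast_conditions(
        fits_a, fits_b,
        delta_threshold=config.delta_threshold, q_threshold=config.q_threshold,
    )
    summary = gradient.zonation_summary(contrasts, fits_a, fits_b)
    logger.info("%d proteins in contrast scope, %d loss calls",
                len(contrasts), int(contrasts["loss"].sum()))
    return {
        "fits_a": fits_a,
        "fits_b": fits_b,
        "contrasts": contrasts,
        "summary": summary,
        "zonation_a": results[condition_a],
        "zonation_b": results[condition_b],
    }
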