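"""End-to-end processing: paired 0-hr/48-hr stacks to differential metrics.

Stages per region pair: preprocess both stacks, detect the gel boundaries
at both timepoints from reflectance, register the 48-hr frame onto the 0-hr
frame via post-corner landmarks, fit the monolayer on the 0-hr combined
cytosolic/transmitted signal (the 0-hr monolayer defines the reference wall;
the curve is carried into the 48-hr frame through the rigid registration),
compute (M, J, AR) for both channels at both timepoints, and take the
growth-positive differentials.  Regions are independent: a failure in one
pair is recorded and the pipeline continues.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import geometry, io, metrics, monolayer, phantom, preprocess
from .config import PipelineConfig

StackLike = Union[str, Path, preprocess.ImageStack]

METRIC_COLUMNS = (
    "M_cyto", "J_cyto", "AR_cyto", "M_hoechst", "J_hoechst", "AR_hoechst",
)


def _load(stack: StackLike) -> preprocess.ImageStack:
    if isinstance(stack, preprocess.ImageStack):
        return stack
    return io.read_stack(stack)


def preprocess_stack(
    stack: preprocess.ImageStack, config: PipelineConfig
) -> preprocess.ImageStack:
    """Median filter, normalize and remove fluorescence background."""
    st, _ = preprocess.preprocess_stack(
        stack,
        median_window=config.median_window,
        background_k_sigma=config.background_k_sigma,
    )
    return st


def detect_region(
    stack: preprocess.ImageStack, config: PipelineConfig
) -> geometry.GelRegion:
    geom = phantom.make_device_geometry(config.geometry)
    refl = np.asarray(stack.channels["reflectance"], dtype=float).mean(axis=0)
    return geometry.detect_gel_boundaries(
        refl,
        geom,
        voxel_size_um=stack.voxel_size_um,
        region_index=stack.region_index,
        n_z=stack.shape[0],
    )


def monolayer_signal(
    stack: preprocess.ImageStack, config: PipelineConfig
) -> np.ndarray:
    """Combined cytosolic + transmitted 2D signal for monolayer fitting.

    Cells attenuate transmitted light, so the transmitted projection is
    inverted before combination (config-selectable).
    """
    cyto = np.asarray(stack.channels["cyto"], dtype=float).mean(axis=0)
    trans = np.asarray(stack.channels["transmitted"], dtype=float).mean(axis=0)
    if config.invert_transmitted:
        trans = trans.max() - trans
    return monolayer.combined_signal(cyto, trans, config.combine_weights)


def process_pair(
    stack_0hr: StackLike,
    stack_48hr: StackLike,
    config: PipelineConfig,
    condition: str = "",
) -> Tuple[metrics.AngiogenicMetrics, metrics.AngiogenicMetrics, metrics.AngiogenicMetrics]:
    """Process one 0-hr/48-hr pair; returns (m0, m48, differential)."""
    s0 = preprocess_stack(_load(stack_0hr), config)
    s48 = preprocess_stack(_load(stack_48hr), config)
    r0 = detect_region(s0, config)
    r48 = detect_region(s48, config)
    transform = geometry.register_timepoints(r0, r48)

    curve0 = monolayer.fit_monolayer(
        monolayer_signal(s0, config), r0, band_halfwidth_um=config.band_halfwidth_um
    )
    if config.refit_monolayer_48hr:
        curve48 = monolayer.fit_monolayer(
            monolayer_signal(s48, config),
            r48,
            band_halfwidth_um=config.band_halfwidth_um,
        )
    else:
        cp48 = transform.inverse().apply(curve0.control_points)
        order = np.argsort(cp48[:, 0])
        curve48 = monolayer.MonolayerCurve(
            cp48[order], band_halfwidth_um=curve0.band_halfwidth_um
        )

    m0 = metrics.compute_metrics(s0, r0, curve0, config.offset_um, config.ar_cap)
    m48 = metrics.compute_metrics(s48, r48, curve48, config.offset_um, config.ar_cap)
    m0 = dataclasses.replace(m0, condition=condition)
    m48 = dataclasses.replace(m48, condition=condition)
    diff = metrics.differential_metrics(m0, m48)
    return m0, m48, diff


def run_pipeline(
    config: PipelineConfig,
    stack_pairs: Sequence[Tuple[StackLike, StackLike]],
    condition: str = "",
) -> Tuple[pd.DataFrame, List[dict]]:
    """Run the full pipeline over paired stacks.

    Returns the long-format ensemble table (one row per region x timepoint,
    timepoints '0hr', '48hr' and 'diff') and a per-pair report.  The
    pipeline is a pure function of (config, inputs): identical inputs give
    identical tables.
    """
    rows: List[dict] = []
    report: List[dict] = []
    for k, (p0, p48) in enumerate(stack_pairs):
        try:
            m0, m48, diff = process_pair(p0, p48, config, condition=condition)
        except Exception as exc:  # regions are independent
            report.append({"pair": k, "status": "failed", "error": str(exc)})
            continue
        report.append({"pair": k, "status": "ok", "error": ""})
        for m in (m0, m48, diff):
            row = {
                "condition": m.condition,
                "device_id": m.device_id,
                "region_index": m.region_index,
                "timepoint": m.timepoint_label,
            }
            row.update({c: getattr(m, c) for c in METRIC_COLUMNS})
            row["flags"] = ";".join(m.flags)
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, report


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6g")
    return path
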