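"""Stack and record I/O: OME-TIFF volumes, ground-truth sidecars, CSV tables."""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile
import yaml

from .phantom import GroundTruth
from .metrics import AngiogenicMetrics
from .preprocess import CHANNEL_ORDER, ImageStack


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-channel OME-TIFF (axes CZYX, float32).

    Channel names and physical voxel sizes go into the OME metadata; the
    timepoint/device/region labels go into a small YAML sidecar next to the
    file (OME has no standard slot for them).
    """
    path = Path(path)
    data = np.stack(
        [np.asarray(stack.channels[c], dtype=np.float32) for c in CHANNEL_ORDER]
    )
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(CHANNEL_ORDER)},
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
        },
    )
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "timepoint_label": stack.timepoint_label,
                "device_id": stack.device_id,
                "region_index": stack.region_index,
            },
            fh,
        )
    return path


def _parse_ome_channels(ome_xml: str) -> list:
    return re.findall(r'<Channel[^>]*\bName="([^"]+)"', ome_xml or "")


def _parse_ome_voxel(ome_xml: str) -> Optional[Tuple[float, float, float]]:
    out = []
    for ax in ("Z", "Y", "X"):
        m = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', ome_xml or "")
        if not m:
            return None
        out.append(float(m.group(1)))
    return tuple(out)  # type: ignore[return-value]


def read_stack(
    path: str | Path,
    channel_names: Optional[Sequence[str]] = None,
    voxel_size_um: Optional[Tuple[float, float, float]] = None,
    **labels,
) -> ImageStack:
    """Read a multi-channel TIFF/OME-TIFF stack.

    Channel names come from the OME metadata unless ``channel_names`` maps
    them explicitly; the voxel size comes from the OME physical sizes unless
    overridden.  Missing channels or an unknown voxel size raise errors
    naming what is required.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tf.ome_metadata or ""
    if data.ndim == 3:
        data = data[None]
        axes = "C" + axes if "C" not in axes else axes
    if data.ndim != 4:
        raise ValueError(f"expected a 4D (C, Z, Y, X) stack, got shape {data.shape}")
    # normalize axis order to CZYX
    axes = axes.replace("S", "C") if "C" not in axes else axes
    order = [axes.index(a) for a in "CZYX" if a in axes]
    if len(order) == 4:
        data = np.transpose(data, order)
    names = list(channel_names) if channel_names else _parse_ome_channels(ome)
    if len(names) != data.shape[0]:
        if channel_names is None and data.shape[0] == len(CHANNEL_ORDER):
            names = list(CHANNEL_ORDER)
        else:
            raise ValueError(
                f"stack has {data.shape[0]} channels; expected the channels "
                f"{list(CHANNEL_ORDER)} or an explicit channel_names mapping"
            )
    missing = set(CHANNEL_ORDER) - set(names)
    if missing:
        raise ValueError(f"missing expected channels: {sorted(missing)}")
    if voxel_size_um is None:
        voxel_size_um = _parse_ome_voxel(ome)
    if voxel_size_um is None:
        raise ValueError(
            "voxel size not present in metadata; pass voxel_size_um=(dz, dy, dx)"
        )
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    meta.update(labels)
    return ImageStack(
        channels={n: data[i] for i, n in enumerate(names)},
        voxel_size_um=tuple(voxel_size_um),
        timepoint_label=str(meta.get("timepoint_label", "0hr")),
        device_id=str(meta.get("device_id", "D0")),
        region_index=int(meta.get("region_index", 0)),
    )


def _yaml_scalar(v):
    if isinstance(v, (np.floating, float)):
        return None if np.isnan(v) else float(v)
    if isinstance(v, np.integer):
        return int(v)
    return v


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Serialize a phantom's ground truth as YAML-compatible structured text."""
    path = Path(path)
    d = {
        "boundary_lines": [list(map(float, l)) for l in truth.boundary_lines],
        "x_mid_um": float(truth.x_mid_um),
        "post_polygons": [p.tolist() for p in truth.post_polygons],
        "monolayer_control_points": truth.monolayer_control_points.tolist(),
        "monolayer_control_points_region": truth.monolayer_control_points_region.tolist(),
        "offset_um": float(truth.offset_um),
        "gel_width_um": float(truth.gel_width_um),
        "period_um": float(truth.period_um),
        "margin_um": float(truth.margin_um),
        "clipped_sprouts": list(truth.clipped_sprouts),
        "metrics_true": {
            k: _yaml_scalar(v)
            for k, v in truth.metrics_true.as_dict().items()
            if k != "flags"
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    md = d["metrics_true"]
    metrics = AngiogenicMetrics(
        **{
            k: (float("nan") if v is None else v)
            for k, v in md.items()
        }
    )
    return GroundTruth(
        boundary_lines=[tuple(l) for l in d["boundary_lines"]],
        x_mid_um=d["x_mid_um"],
        post_polygons=[np.array(p) for p in d["post_polygons"]],
        monolayer_control_points=np.array(d["monolayer_control_points"]),
        monolayer_control_points_region=np.array(
            d["monolayer_control_points_region"]
        ),
        metrics_true=metrics,
        offset_um=d["offset_um"],
        gel_width_um=d["gel_width_um"],
        period_um=d["period_um"],
        margin_um=d["margin_um"],
        clipped_sprouts=tuple(d["clipped_sprouts"]),
    )
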