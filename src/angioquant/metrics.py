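"""Angiogenic growth metrics over the gel invasion region.

The metrics integrate the background-removed fluorescence signals over the
region ``V`` between the detected gel boundaries and the endothelial
monolayer, offset 10 um past the monolayer to exclude the bright cell
aggregation band around it:

* ``M`` — total signal integral over ``V`` (signal x volume); aggregate
  growth from migration and proliferation.
* ``J`` — first moment of the signal with respect to the normal distance
  ``r(x)`` from the monolayer; penetration depth measure.
* ``AR`` — aspect ratio, the signal-weighted mean normal penetration
  divided by the signal-weighted mean lateral spread; directionality of
  invasion along the chemoattractant gradient.

All distances are in micrometres; integrals use the per-axis voxel volume
so anisotropic stacks (coarse z, fine xy) are handled exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import TYPE_CHECKING, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .geometry import GelRegion
    from .monolayer import MonolayerCurve
    from .preprocess import ImageStack


@dataclasses.dataclass
class DistanceField:
    """Per-pixel monolayer coordinates: normal distance r (gel side positive)
    and along-monolayer coordinate u (arclength of the nearest curve point)."""

    r_um: np.ndarray  # (ny, nx)
    u_um: np.ndarray  # (ny, nx)


@dataclasses.dataclass
class RegionMask:
    """Integration region: gel strip, minus posts, past the offset monolayer."""

    mask2d: np.ndarray  # (ny, nx) bool; constant over z
    n_z: int
    offset_um: float
    voxel_size_um: Tuple[float, float, float]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def n_voxels(self) -> int:
        return int(self.mask2d.sum()) * self.n_z


@dataclasses.dataclass
class AngiogenicMetrics:
    """Per-region scalar metrics for the cytosolic and nuclear channels."""

    M_cyto: float = 0.0
    J_cyto: float = 0.0
    AR_cyto: float = float("nan")
    M_hoechst: float = 0.0
    J_hoechst: float = 0.0
    AR_hoechst: float = float("nan")
    timepoint_label: str = ""
    device_id: str = "D0"
    region_index: int = 0
    condition: str = ""
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("M_cyto", "J_cyto", "M_hoechst", "J_hoechst"):
            if getattr(self, name) < -1e-9 and self.timepoint_label != "diff":
                raise ValueError(f"{name}: must be >= 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def signed_distance_to_polyline(
    points: np.ndarray, polyline: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-point distance from 2D points to a dense polyline.

    Returns ``(d, u)`` where ``d`` is the signed normal distance (positive on
    the left of the oriented polyline; callers fix the global sign) and ``u``
    the arclength coordinate of the nearest polyline vertex.  The polyline
    must be sampled densely relative to the required accuracy.
    """
    points = np.asarray(points, dtype=float)
    polyline = np.asarray(polyline, dtype=float)
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    tree = cKDTree(polyline)
    dist, idx = tree.query(points)
    # tangent at the nearest vertex (central difference at interior vertices)
    tang = np.empty_like(polyline)
    tang[1:-1] = polyline[2:] - polyline[:-2]
    tang[0] = polyline[1] - polyline[0]
    tang[-1] = polyline[-1] - polyline[-2]
    t = tang[idx]
    rel = points - polyline[idx]
    cross = t[:, 0] * rel[:, 1] - t[:, 1] * rel[:, 0]
    sign = np.where(cross >= 0, 1.0, -1.0)
    return sign * dist, arclen[idx]


def distance_field(curve: "MonolayerCurve", region: "GelRegion") -> DistanceField:
    """Normal distance and along-monolayer coordinate for every pixel.

    Exact (up to dense sampling of the spline) nearest-point projection;
    the sign convention puts the gel interior at positive ``r``.
    """
    _, ny, nx = region.image_shape
    dz, dy, dx = region.voxel_size_um
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    poly = curve.polyline(step_um=min(dx, dy) / 2.0, x_range=(0.0, nx * dx))
    d, u = signed_distance_to_polyline(pts, poly)
    # calibrate the sign so that the gel interior (midpoint between the two
    # boundary lines, beyond the curve) is positive
    x_mid = nx * dx / 2.0
    y_ref = 0.5 * (region.line_y(0, x_mid) + region.line_y(1, x_mid))
    ref_d, _ = signed_distance_to_polyline(
        np.array([[x_mid, y_ref]]), poly
    )
    flip = -1.0 if ref_d[0] < 0 else 1.0
    return DistanceField(
        r_um=(flip * d).reshape(ny, nx), u_um=u.reshape(ny, nx)
    )


def integration_region(
    region: "GelRegion",
    curve: "MonolayerCurve",
    offset_um: float = 10.0,
    field: Optional[DistanceField] = None,
) -> RegionMask:
    """Build the metric integration region ``V``.

    ``V`` is the gel strip bounded by the two gel/PDMS boundary lines and the
    post polygons, restricted to normal distances ``r >= offset_um`` past the
    monolayer curve.  The default 10 um offset excludes the high-intensity
    band of cell aggregation around the monolayer.
    """
    if offset_um < 0:
        raise ValueError("offset_um: must be >= 0")
    nz, ny, nx = region.image_shape
    dz, dy, dx = region.voxel_size_um
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys)
    y0 = region.line_y(0, xs)[None, :]
    y1 = region.line_y(1, xs)[None, :]
    strip = (Y >= np.minimum(y0, y1)) & (Y <= np.maximum(y0, y1))
    for poly in region.post_polygons:
        strip &= ~_points_in_convex_polygon(X, Y, np.asarray(poly))
    if field is None:
        field = distance_field(curve, region)
    mask = strip & (field.r_um >= offset_um)
    if not mask.any():
        raise ValueError(
            "empty integration region: monolayer at (or past) the far boundary"
        )
    return RegionMask(
        mask2d=mask, n_z=nz, offset_um=float(offset_um),
        voxel_size_um=region.voxel_size_um,
    )


def _points_in_convex_polygon(
    X: np.ndarray, Y: np.ndarray, poly: np.ndarray
) -> np.ndarray:
    """Vectorized membership test for a convex polygon (any orientation)."""
    n = len(poly)
    inside = np.ones(X.shape, dtype=bool)
    # determine orientation once
    area2 = 0.0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        area2 += x1 * y2 - x2 * y1
    ccw = area2 >= 0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cross = (x2 - x1) * (Y - y1) - (y2 - y1) * (X - x1)
        inside &= (cross >= 0) if ccw else (cross <= 0)
    return inside


def total_integral(signal: np.ndarray, mask: RegionMask) -> float:
    """Total signal integral M = sum over V of s(x) dV (signal x um^3)."""
    signal = np.asarray(signal)
    return float(signal[:, mask.mask2d].sum() * mask.voxel_volume_um3)


def first_moment(
    signal: np.ndarray, mask: RegionMask, field: DistanceField
) -> float:
    """First moment J = sum over V of s(x) r(x) dV (signal x um^3 x um)."""
    signal = np.asarray(signal)
    r = field.r_um[mask.mask2d]
    return float((signal[:, mask.mask2d] * r[None, :]).sum() * mask.voxel_volume_um3)


def aspect_ratio(
    signal: np.ndarray,
    mask: RegionMask,
    field: DistanceField,
    cap: float = 100.0,
) -> Tuple[float, Tuple[str, ...]]:
    """Aspect ratio AR = (mean signal-weighted r) / (mean signal-weighted |u - ubar|).

    Dimensionless: grows with directional penetration into the gel relative
    to lateral spreading along the monolayer.  Undefined (NaN, flagged) when
    the total integral vanishes; capped (flagged) when the lateral spread is
    below one pixel (single-column signal).
    """
    signal = np.asarray(signal)
    w = signal[:, mask.mask2d].sum(axis=0)  # collapse z: r, u constant over z
    W = w.sum()
    if W <= 0:
        return float("nan"), ("undefined_ar",)
    r = field.r_um[mask.mask2d]
    u = field.u_um[mask.mask2d]
    r_mean = float((w * r).sum() / W)
    u_bar = float((w * u).sum() / W)
    lateral = float((w * np.abs(u - u_bar)).sum() / W)
    min_px = min(mask.voxel_size_um[1], mask.voxel_size_um[2])
    if lateral < 0.5 * min_px:
        return float(cap), ("ar_capped",)
    return r_mean / lateral, ()


def compute_metrics(
    stack: "ImageStack",
    region: "GelRegion",
    curve: "MonolayerCurve",
    offset_um: float = 10.0,
    ar_cap: float = 100.0,
) -> AngiogenicMetrics:
    """Compute (M, J, AR) for the cytosolic and nuclear channels of a stack.

    If the stack records a normalization transform, the integral metrics are
    rescaled back to the acquisition intensity scale; per-stack min/max
    normalization would otherwise give every region its own arbitrary M/J
    units.  The dimensionless AR is unaffected.
    """
    field = distance_field(curve, region)
    mask = integration_region(region, curve, offset_um, field=field)
    flags: Tuple[str, ...] = ()
    values = {}
    for chan, suffix in (("cyto", "cyto"), ("hoechst", "hoechst")):
        sig = stack.channels[chan]
        scale = stack.norm_transform.get(chan, (0.0, 1.0))[1]
        M = total_integral(sig, mask) * scale
        J = first_moment(sig, mask, field) * scale
        AR, fl = aspect_ratio(sig, mask, field, cap=ar_cap)
        values[f"M_{suffix}"] = M
        values[f"J_{suffix}"] = J
        values[f"AR_{suffix}"] = AR
        flags += tuple(f"{suffix}:{f}" for f in fl)
    return AngiogenicMetrics(
        timepoint_label=stack.timepoint_label,
        device_id=stack.device_id,
        region_index=stack.region_index,
        flags=flags,
        **values,
    )


def differential_metrics(
    m0: AngiogenicMetrics, m48: AngiogenicMetrics
) -> AngiogenicMetrics:
    """Growth-positive differential metrics: delta = value(48hr) - value(0hr).

    Positive deltas indicate net growth over the culture interval.  Both
    records must refer to the same device and region.
    """
    if (m0.device_id, m0.region_index) != (m48.device_id, m48.region_index):
        raise ValueError(
            "identifier mismatch: "
            f"({m0.device_id}, {m0.region_index}) vs "
            f"({m48.device_id}, {m48.region_index})"
        )

    def _diff(a: float, b: float) -> float:
        if math.isnan(a) or math.isnan(b):
            return float("nan")
        return b - a

    return AngiogenicMetrics(
        M_cyto=m48.M_cyto - m0.M_cyto,
        J_cyto=m48.J_cyto - m0.J_cyto,
        AR_cyto=_diff(m0.AR_cyto, m48.AR_cyto),
        M_hoechst=m48.M_hoechst - m0.M_hoechst,
        J_hoechst=m48.J_hoechst - m0.J_hoechst,
        AR_hoechst=_diff(m0.AR_hoechst, m48.AR_hoechst),
        timepoint_label="diff",
        device_id=m0.device_id,
        region_index=m0.region_index,
        condition=m0.condition or m48.condition,
        flags=m0.flags + m48.flags,
    )
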