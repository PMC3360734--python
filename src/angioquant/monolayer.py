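"""Endothelial monolayer localization.

The monolayer is the confluent band of endothelial cells lining the gel
interface; it defines the origin of the normal coordinate r used by the
penetration metrics.  It is located as the 4-control-point natural cubic
spline that maximizes the band-integral of a combined cytosolic/transmitted
signal, searched with multi-start Nelder-Mead over the four normal offsets
of the control points (knots are fixed and evenly spaced along the
monolayer, so the curve is single-valued and fold-free by construction).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import TYPE_CHECKING, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import GelRegion


@dataclasses.dataclass
class MonolayerCurve:
    """A 4-control-point natural cubic spline in image coordinates (um)."""

    control_points: np.ndarray  # (4, 2) columns (x_um, y_um)
    band_halfwidth_um: float = 10.0
    score: float = float("nan")
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        if cp.shape != (4, 2):
            raise ValueError("control_points: expected shape (4, 2)")
        if np.any(np.diff(cp[:, 0]) <= 0):
            raise ValueError("control_points: x positions must be increasing")
        self.control_points = cp

    def spline(self) -> CubicSpline:
        cp = self.control_points
        return CubicSpline(cp[:, 0], cp[:, 1], bc_type="natural")

    def polyline(
        self, step_um: float = 1.0, x_range: Optional[Tuple[float, float]] = None
    ) -> np.ndarray:
        """Dense samples of the curve; extrapolates the natural spline if the
        requested range exceeds the control-point span."""
        if x_range is None:
            x_range = (self.control_points[0, 0], self.control_points[-1, 0])
        n = max(int(np.ceil((x_range[1] - x_range[0]) / step_um)) + 1, 2)
        xs = np.linspace(x_range[0], x_range[1], n)
        return np.column_stack([xs, self.spline()(xs)])

    def shifted(self, dy_um: float) -> "MonolayerCurve":
        cp = self.control_points.copy()
        cp[:, 1] += dy_um
        return dataclasses.replace(self, control_points=cp)


def combined_signal(
    cyto: np.ndarray,
    transmitted: np.ndarray,
    weights: Tuple[float, float] = (0.7, 0.3),
) -> np.ndarray:
    """Weighted sum of the two 2D projections, renormalized to [0, 1]."""
    cyto = np.asarray(cyto, dtype=float)
    transmitted = np.asarray(transmitted, dtype=float)
    if cyto.shape != transmitted.shape:
        raise ValueError(
            f"shape mismatch: {cyto.shape} vs {transmitted.shape}"
        )
    w0, w1 = weights
    if w0 < 0 or w1 < 0 or (w0 == 0 and w1 == 0):
        raise ValueError("weights: must be >= 0 and not both zero")
    f = w0 * cyto + w1 * transmitted
    lo, hi = float(f.min()), float(f.max())
    if hi - lo <= 0:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def band_integral(
    curve: MonolayerCurve | np.ndarray,
    signal: np.ndarray,
    halfwidth_um: float = 10.0,
    voxel_size_um: Tuple[float, float] = (1.0, 1.0),
    exclude: Optional[np.ndarray] = None,
) -> float:
    """Mean signal within normal distance ``halfwidth_um`` of the curve.

    The integral is normalized by the area of a straight reference band
    (2 x halfwidth x image width).  Candidate curves are single-valued over
    a fixed along-monolayer span, so normalizing by the actual curved-band
    area would penalize curve length and bias the fit toward flattened
    monolayers, while a longer-curve advantage cannot arise.  ``exclude``
    drops pixels (e.g. PDMS post footprints) from both numerator and
    denominator.  Bands exiting the image are clipped (flagged with a
    warning).
    """
    if not isinstance(curve, MonolayerCurve):
        curve = MonolayerCurve(np.asarray(curve, dtype=float))
    signal = np.asarray(signal, dtype=float)
    ny, nx = signal.shape
    dy, dx = voxel_size_um
    poly = curve.polyline(step_um=min(dx, dy) / 2.0, x_range=(0.0, nx * dx))
    y_curve = poly[:, 1]
    if y_curve.min() - halfwidth_um < 0 or y_curve.max() + halfwidth_um > ny * dy:
        warnings.warn("band exits image; clipped")
    # restrict to rows that can intersect the band
    px = min(dx, dy)
    row_lo = max(int((y_curve.min() - halfwidth_um) / dy) - 1, 0)
    row_hi = min(int((y_curve.max() + halfwidth_um) / dy) + 2, ny)
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(row_lo, row_hi) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys)
    tree = cKDTree(poly)
    dist, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    member = np.clip((halfwidth_um + 0.5 * px - dist) / px, 0.0, 1.0)
    denom = 2.0 * halfwidth_um * nx / dy  # straight-band pixel count
    if exclude is not None:
        keep = (~np.asarray(exclude[row_lo:row_hi], dtype=bool)).ravel()
        denom -= float((member * ~keep.astype(bool)).sum())
        member = member * keep
    if denom <= 0:
        return 0.0
    return float((signal[row_lo:row_hi].ravel() * member).sum() / denom)


def fit_monolayer(
    signal: np.ndarray,
    region: "GelRegion",
    init: Optional[MonolayerCurve] = None,
    band_halfwidth_um: float = 10.0,
    start_offsets_um: Sequence[float] = (0.0, 25.0, 60.0),
    maxiter: int = 150,
) -> MonolayerCurve:
    """Fit the monolayer spline by maximizing the band integral.

    Control points sit at 4 fixed, evenly spaced x positions and move only
    along the gel normal; the search is multi-start Nelder-Mead over the
    four normal offsets, started from a straight line at the monolayer-side
    edge of the gel strip (plus coarser offsets deeper into the gel).  A
    final refinement pass at half the band width removes the positional
    plateau that a band wider than the monolayer leaves.  Ties between
    starts are broken toward the initialization and flagged.
    """
    _, ny, nx = region.image_shape
    dz, dy, dx = region.voxel_size_um
    exclude = None
    width_x = nx * dx
    knots_x = np.linspace(0.5 * dx, width_x - 0.5 * dx, 4)
    y_lo = region.line_y(0, knots_x)
    y_hi = region.line_y(1, knots_x)
    gel_w = np.abs(y_hi - y_lo)
    direction = np.sign(y_hi - y_lo)  # gel interior direction from line 0

    if init is None:
        r_init = np.full(4, band_halfwidth_um)
    else:
        r_init = (init.spline()(knots_x) - y_lo) * direction

    def curve_from_r(r: np.ndarray) -> MonolayerCurve:
        cp = np.column_stack([knots_x, y_lo + direction * r])
        return MonolayerCurve(
            cp, band_halfwidth_um=band_halfwidth_um
        )

    def objective(r: np.ndarray, halfwidth: float = band_halfwidth_um) -> float:
        # penalize control points leaving the gel strip
        penalty = float(
            np.sum(np.clip(1.0 - r, 0, None) + np.clip(r - (gel_w - 1.0), 0, None))
        )
        score = band_integral(
            curve_from_r(np.clip(r, 1.0, gel_w - 1.0)),
            signal,
            halfwidth_um=halfwidth,
            voxel_size_um=(dy, dx),
            exclude=exclude,
        )
        return -(score - 0.1 * penalty)

    results = []
    for k, off in enumerate(start_offsets_um):
        x0 = np.clip(r_init + off, 1.0, gel_w - 1.0)
        if off > 0 and np.all(x0 >= gel_w - 1.0):
            continue  # start would be outside the strip
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 0.05, "fatol": 1e-7},
        )
        results.append((float(-res.fun), k, res.x))
    if not results:
        raise RuntimeError("optimizer failed on every start")
    best_score = max(r[0] for r in results)
    ties = [r for r in results if best_score - r[0] < 1e-9]
    flags: Tuple[str, ...] = ()
    if len(ties) > 1:
        flags = ("tie_broken_toward_init",)
    score, _, r_best = min(ties, key=lambda t: t[1])  # earliest start = init side
    init_score = -objective(r_init)
    if score < init_score - 1e-12:  # pragma: no cover - NM never degrades x0
        score, r_best = init_score, r_init
    # refinement at half band width: a band wider than the monolayer scores
    # identically over a range of positions; the narrow band centers the fit
    narrow = max(band_halfwidth_um / 2.0, 2.0 * min(dy, dx))
    res2 = minimize(
        lambda r: objective(r, narrow),
        r_best,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 0.02, "fatol": 1e-8},
    )
    refined_score = -objective(res2.x)
    if refined_score >= score - 1e-9:
        score, r_best = refined_score, res2.x
    curve = curve_from_r(np.clip(r_best, 1.0, gel_w - 1.0))
    curve.score = score
    curve.flags = flags
    return curve
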