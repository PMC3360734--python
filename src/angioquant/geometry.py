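"""Gel region detection and timepoint registration.

The reflectance channel contrasts the collagen gel (dark) against PDMS
structures (bright), producing a bimodal pixel-intensity histogram.  The two
straight boundary lines delimiting the gel strip are found by maximizing the
separation between the candidate inside/outside intensity distributions
(difference of means), searched with multi-start Nelder-Mead over (offset,
angle) per line from a geometry-informed initialization.  Trapezoidal post
footprints along each boundary provide corner landmarks used to compute the
rigid transform registering the 0-hr and 48-hr acquisitions of the same
physical region.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .phantom import DeviceGeometry


@dataclasses.dataclass
class GelRegion:
    """One detected cell-growth region and its coordinate frame.

    ``boundary_lines`` are (offset_um, angle_deg) pairs parameterizing
    ``y(x) = offset + tan(angle) (x - x_mid)``; line 0 is the monolayer-side
    boundary (smaller offset), the gel interior lies between the two lines.
    """

    boundary_lines: List[Tuple[float, float]]
    x_mid_um: float
    post_polygons: List[np.ndarray]
    region_index: int
    image_shape: Tuple[int, int, int]  # (nz, ny, nx)
    voxel_size_um: Tuple[float, float, float]
    score: float = float("nan")
    flags: Tuple[str, ...] = ()
    landmark_points: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty((0, 2))
    )

    def line_y(self, i: int, x_um):
        off, ang = self.boundary_lines[i]
        return off + math.tan(math.radians(ang)) * (np.asarray(x_um, dtype=float) - self.x_mid_um)

    @property
    def gel_width_um(self) -> float:
        return abs(self.boundary_lines[1][0] - self.boundary_lines[0][0])

    def landmarks(self) -> np.ndarray:
        """Interior post base corners (line index order, then left to right)."""
        return self.landmark_points


@dataclasses.dataclass
class RigidTransform:
    """Rigid map (rotation about the origin + translation) taking 48-hr
    coordinates into the 0-hr frame; stage repositioning only, so rotations
    beyond ~10 degrees indicate a region mismatch."""

    translation_um: np.ndarray  # (dx, dy)
    rotation_deg: float
    residual_um: float = 0.0

    def __post_init__(self) -> None:
        self.translation_um = np.asarray(self.translation_um, dtype=float)
        if abs(self.rotation_deg) >= 10.0:
            warnings.warn(
                f"rotation {self.rotation_deg:.2f} deg exceeds stage repositioning "
                "range; possible region mismatch"
            )

    @property
    def matrix(self) -> np.ndarray:
        a = math.radians(self.rotation_deg)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts) @ self.matrix.T + self.translation_um

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        return RigidTransform(
            translation_um=-(R.T @ self.translation_um),
            rotation_deg=-self.rotation_deg,
            residual_um=self.residual_um,
        )


def _otsu_threshold(img: np.ndarray, bins: int = 256) -> float:
    v = np.asarray(img, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    best, thr = -1.0, centers[len(centers) // 2]
    csum = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    mu_t = cmean[-1] / total
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = csum / total
        mu0 = cmean / csum
        mu1 = (cmean[-1] - cmean) / (total - csum)
        var_b = w0 * (1 - w0) * (mu0 - mu1) ** 2
    var_b = np.nan_to_num(var_b)
    i = int(np.argmax(var_b))
    if var_b[i] > best:
        thr = centers[i]
    return float(thr)


def bimodality_ratio(img: np.ndarray) -> float:
    """Mode separation over intra-mode spread for an intensity image.

    Splits the histogram at the Otsu threshold and reports
    (mu_hi - mu_lo) / max(sd_lo, sd_hi).  Gel/PDMS reflectance images are
    strongly bimodal (ratio >> 4); a ratio below 2 means the contrast is
    insufficient for boundary detection.
    """
    v = np.asarray(img, dtype=float).ravel()
    if v.max() - v.min() <= 0:
        return 0.0
    thr = _otsu_threshold(v)
    lo, hi = v[v <= thr], v[v > thr]
    if len(lo) < 0.01 * len(v) or len(hi) < 0.01 * len(v):
        return 0.0
    sep = float(hi.mean() - lo.mean())
    intra = max(float(lo.std()), float(hi.std()), 1e-12)
    return sep / intra


def separation_score(
    boundary: Tuple[float, float],
    reflectance: np.ndarray,
    voxel_size_um: Tuple[float, float] = (1.0, 1.0),
    x_mid_um: Optional[float] = None,
    window_um: Optional[float] = None,
    exclude: Optional[np.ndarray] = None,
) -> float:
    """Separation objective for one candidate boundary line.

    The line (offset_um, angle_deg) partitions the image (optionally only a
    band of half-width ``window_um`` around the line) into two sides; the
    score is the absolute difference of the mean intensities.  Pixel
    membership is blended linearly over one pixel so the objective is smooth
    in the line parameters.  ``exclude`` masks pixels (e.g. post footprints)
    out of both distributions.  An empty partition scores 0 (with a warning).
    """
    reflectance = np.asarray(reflectance, dtype=float)
    ny, nx = reflectance.shape
    dy, dx = voxel_size_um
    off, ang = boundary
    if x_mid_um is None:
        x_mid_um = nx * dx / 2.0
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    line = off + math.tan(math.radians(ang)) * (xs - x_mid_um)
    d = ys[:, None] - line[None, :]  # signed distance (y units)
    px = min(dy, dx)
    m_above = np.clip(0.5 + d / px, 0.0, 1.0)
    w = np.ones_like(d)
    if window_um is not None:
        w = (np.abs(d) <= window_um).astype(float)
    if exclude is not None:
        w = w * (~np.asarray(exclude, dtype=bool))
    wa = (w * m_above).sum()
    wb = (w * (1 - m_above)).sum()
    if wa < 1.0 or wb < 1.0:
        warnings.warn("candidate boundary produces an empty partition")
        return 0.0
    mean_above = (reflectance * w * m_above).sum() / wa
    mean_below = (reflectance * w * (1 - m_above)).sum() / wb
    return float(abs(mean_above - mean_below))


def detect_gel_boundaries(
    reflectance: np.ndarray,
    geom: DeviceGeometry,
    voxel_size_um: Optional[Tuple[float, float]] = None,
    region_index: int = 0,
    n_z: int = 1,
) -> GelRegion:
    """Detect the two gel/PDMS boundary lines of one region.

    ``reflectance`` is the 2D mean-z projection of the reflectance channel
    (boundaries and posts are vertical structures spanning the full depth).
    Each line is found independently by multi-start Nelder-Mead over
    (offset, angle), maximizing the separation score within a band around
    the candidate; initialization comes from the row-mean intensity profile
    and the expected gel width.  Post footprints are then localized along
    each line by template matching of the bright trapezoid bases.
    """
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.ndim == 3:
        reflectance = reflectance.mean(axis=0)
    ny, nx = reflectance.shape
    if voxel_size_um is None:
        voxel_size_um = geom.voxel_size_um
    if len(voxel_size_um) == 3:
        dz, dy, dx = voxel_size_um
    else:
        dy, dx = voxel_size_um
        dz = geom.voxel_size_um[0]
    if bimodality_ratio(reflectance) < 2.0:
        raise ValueError("gel/PDMS contrast insufficient: histogram not bimodal")
    x_mid = nx * dx / 2.0

    # geometry-informed initialization: gel rows are dark
    thr = _otsu_threshold(reflectance)
    row_mean = reflectance.mean(axis=1)
    gel_rows = np.where(row_mean < thr)[0]
    if len(gel_rows) == 0:
        raise ValueError("gel/PDMS contrast insufficient: no dark gel band")
    y0_init = (gel_rows[0] + 0.5) * dy
    y1_init = (gel_rows[-1] + 0.5) * dy
    window = float(np.clip(0.25 * (y1_init - y0_init), 10 * dy, 60.0))

    def search_line(y_init: float, exclude=None):
        best = None
        for doff in (-2 * dy, 0.0, 2 * dy):
            x0 = np.array([y_init + doff, 0.0])
            # explicit simplex: NM's default perturbation of a zero angle is
            # infinitesimal and would never explore the angle dimension
            simplex = np.array([x0, x0 + [3 * dy, 0.0], x0 + [0.0, 1.5]])
            res = minimize(
                lambda p: -separation_score(
                    (p[0], p[1]), reflectance, (dy, dx), x_mid, window, exclude
                ),
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": 300,
                    "xatol": 0.02,
                    "fatol": 1e-8,
                    "initial_simplex": simplex,
                },
            )
            cand = (float(-res.fun), float(res.x[0]), float(res.x[1]))
            # ties broken toward the smaller |angle|
            if best is None or cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and abs(cand[2]) < abs(best[2])
            ):
                best = cand
        return best

    # pass 1: lines with the bright post bases still inside the gel side;
    # their footprints bias the separation objective a few pixels inward
    first = [search_line(y0_init), search_line(y1_init)]
    first.sort(key=lambda t: t[1])
    lines1 = [(b[1], b[2]) for b in first]
    polys1, _ = _detect_posts(reflectance, lines1, x_mid, geom, (dy, dx))
    # pass 2: refine with post footprints excluded from both distributions
    exclude = _polygon_mask(polys1, reflectance.shape, (dy, dx))
    refined = [search_line(b[1], exclude) for b in first]
    refined.sort(key=lambda t: t[1])
    scores = [b[0] for b in refined]
    lines = [(b[1], b[2]) for b in refined]

    polys, lm = _detect_posts(reflectance, lines, x_mid, geom, (dy, dx))
    return GelRegion(
        boundary_lines=lines,
        x_mid_um=x_mid,
        post_polygons=polys,
        region_index=region_index,
        image_shape=(n_z, ny, nx),
        voxel_size_um=(dz, dy, dx),
        score=float(np.mean(scores)),
        landmark_points=lm,
    )


def _detect_posts(
    reflectance: np.ndarray,
    lines: List[Tuple[float, float]],
    x_mid: float,
    geom: DeviceGeometry,
    voxel_size: Tuple[float, float],
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Locate bright trapezoidal post bases along each boundary line and
    build their polygons from the known post depth and base angle.

    Returns the post polygons plus the interior base corners (corners whose
    brightness crossing falls strictly inside the image) used as
    registration landmarks.
    """
    dy, dx = voxel_size
    ny, nx = reflectance.shape
    xs = (np.arange(nx) + 0.5) * dx
    inset = geom.post_depth_um / math.tan(math.radians(geom.post_base_angle_deg))
    polys: List[np.ndarray] = []
    landmarks: List[Tuple[float, float]] = []
    for li, (off, ang) in enumerate(lines):
        gel_dir = 1.0 if li == 0 else -1.0  # gel interior side of the line
        line_y = off + math.tan(math.radians(ang)) * (xs - x_mid)
        # mean brightness in a shallow band just inside the gel: bright
        # columns mark post bases
        from scipy.ndimage import map_coordinates

        depths = np.linspace(1.5 * dy, 0.45 * geom.post_depth_um, 4)
        prof = np.zeros(nx)
        for d in depths:
            yy = np.clip((line_y + gel_dir * d) / dy - 0.5, 0, ny - 1)
            prof += map_coordinates(
                reflectance, [yy, np.arange(nx, dtype=float)], order=1
            )
        prof /= len(depths)
        # the trapezoid narrows with depth, so the averaged-profile crossing
        # sits mean(depth) * tan(edge-from-vertical angle) inside the true
        # base corner; the edge angle includes the detected line rotation
        d_mean = float(depths.mean())
        alpha0 = math.radians(90.0 - geom.post_base_angle_deg)
        rho = gel_dir * math.radians(ang)
        corr_rising = d_mean * math.tan(alpha0 - rho)
        corr_falling = d_mean * math.tan(alpha0 + rho)
        mid = 0.5 * (GEL_LEVEL + PDMS_LEVEL)
        bright = prof > mid
        edges = np.flatnonzero(np.diff(bright.astype(int)))
        starts = [0] if bright[0] else []
        stops = []
        for e in edges:
            if bright[e + 1]:
                starts.append(e + 1)
            else:
                stops.append(e + 1)
        if bright[-1]:
            stops.append(nx)
        for s, e in zip(starts, stops):
            if e - s < 2:
                continue
            xl = _subpixel_edge(prof, s, mid, dx, rising=True) - corr_rising
            xr = _subpixel_edge(prof, e - 1, mid, dx, rising=False) + corr_falling
            yl = off + math.tan(math.radians(ang)) * (xl - x_mid)
            yr = off + math.tan(math.radians(ang)) * (xr - x_mid)
            d = geom.post_depth_um * gel_dir
            # edge-clipped posts can be narrower than twice the taper inset;
            # collapse the converging side to keep the polygon simple
            xtl, xtr = xl + inset, xr - inset
            if xtl > xtr:
                xtl = xtr = 0.5 * (xtl + xtr)
            polys.append(
                np.array(
                    [
                        [xl, yl],
                        [xr, yr],
                        [xtr, yr + d],
                        [xtl, yl + d],
                    ]
                )
            )
            if s > 0:
                landmarks.append((xl, yl))
            if e < nx:
                landmarks.append((xr, yr))
    return polys, np.array(landmarks) if landmarks else np.empty((0, 2))


GEL_LEVEL = 0.2
PDMS_LEVEL = 0.8


def _polygon_mask(
    polys: List[np.ndarray], shape: Tuple[int, int], voxel_size: Tuple[float, float]
) -> np.ndarray:
    """Boolean footprint of the polygons on the pixel grid, dilated by 2 px."""
    from scipy import ndimage

    dy, dx = voxel_size
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys)
    mask = np.zeros(shape, dtype=bool)
    for poly in polys:
        inside = np.ones(shape, dtype=bool)
        n = len(poly)
        area2 = sum(
            poly[i, 0] * poly[(i + 1) % n, 1] - poly[(i + 1) % n, 0] * poly[i, 1]
            for i in range(n)
        )
        ccw = area2 >= 0
        for i in range(n):
            x1, y1 = poly[i]
            x2, y2 = poly[(i + 1) % n]
            cross = (x2 - x1) * (Y - y1) - (y2 - y1) * (X - x1)
            inside &= (cross >= 0) if ccw else (cross <= 0)
        mask |= inside
    return ndimage.binary_dilation(mask, iterations=2)


def _subpixel_edge(
    prof: np.ndarray, idx: int, level: float, dx: float, rising: bool
) -> float:
    """Linear-interpolated crossing of ``level`` near column ``idx``."""
    n = len(prof)
    if rising:
        i0, i1 = max(idx - 1, 0), idx
    else:
        i0, i1 = idx, min(idx + 1, n - 1)
    p0, p1 = prof[i0], prof[i1]
    if p1 == p0:
        frac = 0.5
    else:
        frac = (level - p0) / (p1 - p0)
    frac = float(np.clip(frac, 0.0, 1.0))
    return (i0 + frac + 0.5) * dx


def register_timepoints(
    region_0hr: GelRegion, region_48hr: GelRegion
) -> RigidTransform:
    """Least-squares rigid transform mapping 48-hr landmarks onto 0-hr ones.

    Landmarks are the post base corners on the detected boundary lines,
    paired in sorted order (valid for the small stage shifts expected when
    re-imaging the same region).  Residual RMS above 10 um triggers a
    region-mismatch warning.
    """
    p0 = region_0hr.landmarks()
    p1 = region_48hr.landmarks()
    if len(p0) == 0 or len(p1) == 0:
        raise ValueError("no landmarks detected; cannot register")
    if len(p0) != len(p1):
        raise ValueError(
            f"landmark count mismatch: {len(p0)} vs {len(p1)}; "
            "regions may not correspond"
        )
    c0 = p0.mean(axis=0)
    c1 = p1.mean(axis=0)
    H = (p1 - c1).T @ (p0 - c0)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    t = c0 - R @ c1
    rot = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    mapped = p1 @ R.T + t
    residual = float(np.sqrt(((mapped - p0) ** 2).sum(axis=1).mean()))
    if residual > 10.0:
        warnings.warn(
            f"registration residual {residual:.1f} um > 10 um: possible region "
            "mismatch"
        )
    return RigidTransform(translation_um=t, rotation_deg=rot, residual_um=residual)
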