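"""Synthetic device phantoms with analytic ground truth.

Generates 4-channel volumetric stacks emulating one gel growth region of the
microfluidic device: a reflectance channel contrasting the collagen gel
against PDMS (posts and channel floor), a cytosolic channel carrying the
endothelial monolayer band and sprout-like cylinders invading the gel, a
nuclear channel with ellipsoidal nuclei strung along each sprout, and a
transmitted-light channel attenuated by the same structures.  Every phantom
carries its exact geometric primitives and closed-form/quadrature metric
values, so the whole detection-and-metrics pipeline can be validated against
analytic truth.

Coordinate convention (shared by all modules): x along the channel axis,
y across the gel (normal to the monolayer at rest), z along the optical
axis; voxel centers at (i + 0.5) * voxel_size; all physical quantities in
micrometres.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .metrics import AngiogenicMetrics, signed_distance_to_polyline
from .monolayer import MonolayerCurve
from .preprocess import ImageStack

GEL_REFLECTANCE = 0.2
PDMS_REFLECTANCE = 0.8


@dataclasses.dataclass(frozen=True)
class DeviceGeometry:
    """Geometry of the ensemble device.

    Defaults describe the reference device: 37 gel growth regions caged by
    trapezoidal PDMS posts with 60 degree base angles (supplementary to the
    ~120 degree contact angle of liquid collagen on treated PDMS), posts
    spaced 100 um at their nearest points, a 1.3 mm wide gel strip, and
    ~160 um imaging depth over 19 z-sections.
    """

    n_regions: int = 37
    post_spacing_um: float = 100.0
    post_base_width_um: float = 50.0
    post_depth_um: float = 30.0
    post_base_angle_deg: float = 60.0
    gel_width_um: float = 1300.0
    channel_width_um: float = 500.0
    stack_depth_um: float = 160.0
    n_z_sections: int = 19
    voxel_size_um: Tuple[float, float, float] = (8.5, 1.25, 1.25)

    def __post_init__(self) -> None:
        checks = {
            "n_regions": self.n_regions >= 1,
            "post_spacing_um": self.post_spacing_um > 0,
            "post_base_width_um": self.post_base_width_um > 0,
            "post_depth_um": self.post_depth_um > 0,
            "post_base_angle_deg": 0 < self.post_base_angle_deg < 90,
            "gel_width_um": self.gel_width_um > 0,
            "channel_width_um": self.channel_width_um > 0,
            "stack_depth_um": self.stack_depth_um > 0,
            "n_z_sections": self.n_z_sections >= 1,
            "voxel_size_um": all(v > 0 for v in self.voxel_size_um),
        }
        for field, ok in checks.items():
            if not ok:
                raise ValueError(
                    f"{field}: value {getattr(self, field)!r} violates geometry "
                    "invariants"
                )
        if self.post_top_width_um <= 0:
            raise ValueError(
                "post_depth_um: post converges to zero width before reaching "
                f"depth {self.post_depth_um}"
            )
        if self.post_depth_um >= self.gel_width_um / 2:
            raise ValueError("post_depth_um: posts may not span the gel strip")

    @property
    def period_um(self) -> float:
        """Length of one growth region along the channel axis."""
        return self.post_spacing_um + self.post_base_width_um

    @property
    def post_top_width_um(self) -> float:
        inset = self.post_depth_um / math.tan(
            math.radians(self.post_base_angle_deg)
        )
        return self.post_base_width_um - 2.0 * inset


def make_device_geometry(
    overrides: Optional[Mapping[str, object]] = None,
) -> DeviceGeometry:
    """Build a device geometry; unspecified fields keep the reference values."""
    overrides = dict(overrides or {})
    valid = {f.name for f in dataclasses.fields(DeviceGeometry)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown geometry parameters: {sorted(unknown)}")
    return DeviceGeometry(**overrides)  # type: ignore[arg-type]


@dataclasses.dataclass(frozen=True)
class SproutSpec:
    """One sprout-like object: a capped cylinder of cytosolic signal rooted on
    the monolayer, with optional ellipsoidal nuclei strung along its axis.

    ``base_point`` is (u, r) in region coordinates (u along the monolayer,
    r normal into the gel from the monolayer-side boundary); ``r = None``
    places the base exactly on the monolayer curve.  ``direction_deg`` is
    measured from the monolayer normal (0 = straight into the gel).
    """

    base_point: Tuple[float, Optional[float]]
    length_um: float
    radius_um: float
    direction_deg: float = 0.0
    cyto_intensity: float = 1.0
    n_nuclei: int = 0
    nucleus_intensity: float = 1.0
    nucleus_semiaxes_um: Tuple[float, float, float] = (3.5, 3.5, 6.0)
    """Semi-axes (z, in-plane transverse, along-axis) of each nucleus."""

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise ValueError("length_um: must be >= 0")
        if self.radius_um <= 0:
            raise ValueError("radius_um: must be > 0")
        if self.cyto_intensity < 0 or self.nucleus_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei: must be >= 0")

    def nucleus_axial_positions(self) -> np.ndarray:
        """Deterministic nucleus centers along the axis: t_i = (i+1/2) L / n."""
        if self.n_nuclei == 0:
            return np.empty(0)
        i = np.arange(self.n_nuclei)
        return (i + 0.5) * self.length_um / self.n_nuclei


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian background noise (the only noise model supported)."""

    background_mean: float = 0.1
    background_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background_sd: must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Exact primitives and analytic metrics of a rendered phantom."""

    boundary_lines: List[Tuple[float, float]]  # (offset_um, angle_deg) per line
    x_mid_um: float
    post_polygons: List[np.ndarray]  # image-frame (x, y) um vertices
    monolayer_control_points: np.ndarray  # (4, 2) image-frame um
    monolayer_control_points_region: np.ndarray  # (4, 2) region (u, r) um
    metrics_true: AngiogenicMetrics
    offset_um: float
    gel_width_um: float
    period_um: float
    margin_um: float
    clipped_sprouts: Tuple[int, ...] = ()

    def line_y(self, i: int, x_um: np.ndarray | float) -> np.ndarray | float:
        off, ang = self.boundary_lines[i]
        return off + math.tan(math.radians(ang)) * (np.asarray(x_um) - self.x_mid_um)


# ---------------------------------------------------------------------------
# analytic ground-truth metrics


def cylinder_integrals(
    intensity: float, radius_um: float, length_um: float, offset_um: float
) -> Tuple[float, float]:
    """Closed-form (M, J) of a uniform cylinder normal to a straight monolayer.

    M = s pi rho^2 (L - d) and J = s pi rho^2 (L^2 - d^2) / 2 for offset
    d < L, both zero otherwise; r is measured from the monolayer.
    """
    if offset_um >= length_um:
        return 0.0, 0.0
    a = intensity * math.pi * radius_um**2
    M = a * (length_um - offset_um)
    J = a * (length_um**2 - offset_um**2) / 2.0
    return M, J


def _sphere_cap_fraction(tau: np.ndarray) -> np.ndarray:
    """Volume fraction of a unit ball beyond the plane t = tau."""
    tau = np.clip(tau, -1.0, 1.0)
    return (2.0 - 3.0 * tau + tau**3) / 4.0


def _sphere_cap_moment(tau: np.ndarray) -> np.ndarray:
    """First moment of t (about the center) of a unit ball beyond t = tau."""
    tau = np.clip(tau, -1.0, 1.0)
    return 3.0 * (1.0 - tau**2) ** 2 / 16.0


def _monolayer_polyline_region(
    control_points: np.ndarray, u_range: Tuple[float, float], step: float = 0.25
) -> np.ndarray:
    curve = MonolayerCurve(np.asarray(control_points, dtype=float))
    return curve.polyline(step_um=step, x_range=u_range)


def _cylinder_quadrature(
    spec: SproutSpec,
    poly: np.ndarray,
    offset_um: float,
    base_r: float,
    nt: int = 240,
    nr: int = 12,
    na: int = 24,
) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """Deterministic quadrature of (M, J) and weighted (u, w) samples for a
    capped cylinder against an arbitrary monolayer polyline."""
    phi = math.radians(spec.direction_deg)
    axis = np.array([math.sin(phi), math.cos(phi)])  # (u, r) components
    e1 = np.array([math.cos(phi), -math.sin(phi)])  # in-plane transverse
    base = np.array([spec.base_point[0], base_r])
    t = (np.arange(nt) + 0.5) * spec.length_um / nt
    rr = (np.arange(nr) + 0.5) * spec.radius_um / nr
    aa = (np.arange(na) + 0.5) * 2 * math.pi / na
    # polar sampling of the cross-section disc: the area element r dr da,
    # with positions projected onto the in-plane transverse axis, integrates
    # any function of (u, r) over the full 3D cylinder (z drops out because
    # the monolayer distance is independent of depth)
    RR, AA = np.meshgrid(rr, aa, indexing="ij")
    in_plane = RR * np.cos(AA)
    w_cell = (RR * (spec.radius_um / nr) * (2 * math.pi / na))
    pts_u = base[0] + t[:, None] * axis[0] + (in_plane * e1[0]).ravel()[None, :]
    pts_r = base[1] + t[:, None] * axis[1] + (in_plane * e1[1]).ravel()[None, :]
    pts = np.column_stack([pts_u.ravel(), pts_r.ravel()])
    d, u = signed_distance_to_polyline(pts, poly)
    # orient positive toward the gel (direction of the sprout axis)
    probe = base + axis * max(spec.length_um, 1.0)
    pd, _ = signed_distance_to_polyline(probe[None, :], poly)
    if pd[0] < 0:
        d = -d
    w = np.broadcast_to(
        w_cell.ravel()[None, :] * (spec.length_um / nt), pts_u.shape
    ).ravel()
    inside = d >= offset_um
    s = spec.cyto_intensity
    M = float(s * w[inside].sum())
    J = float(s * (w[inside] * d[inside]).sum())
    return M, J, u[inside], s * w[inside]


def _nucleus_ellipsoid_samples(
    spec: SproutSpec, n: int = 12
) -> Tuple[np.ndarray, np.ndarray]:
    """Midpoint-grid samples of a unit ball, scaled to the nucleus semi-axes.

    Returns principal-frame coordinates (m, 3) ordered (along-axis,
    transverse, z) and equal weights summing to the ellipsoid volume.
    """
    az, aperp, apar = spec.nucleus_semiaxes_um
    g = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    P, Q, Z = np.meshgrid(g, g, g, indexing="ij")
    inside = P**2 + Q**2 + Z**2 <= 1.0
    pts = np.column_stack([P[inside] * apar, Q[inside] * aperp, Z[inside] * az])
    cell = (2.0 / n) ** 3 * apar * aperp * az
    return pts, np.full(len(pts), cell)


def ground_truth_metrics(
    sprouts: Sequence[SproutSpec],
    monolayer_control_points: np.ndarray,
    offset_um: float = 10.0,
) -> AngiogenicMetrics:
    """Analytic metrics of a sprout list, independent of any rendering.

    Cytosolic M and J use the closed-form cylinder expressions when the
    monolayer is straight and the sprout is normal to it, and a deterministic
    cylindrical quadrature otherwise.  Nuclear M and J are exact (ellipsoid
    plane-cap formulas).  Aspect ratios use the same machinery plus the
    lateral first moment.
    """
    if offset_um < 0:
        raise ValueError("offset_um: must be >= 0")
    cps = np.asarray(monolayer_control_points, dtype=float)
    sprouts = list(sprouts)
    if not sprouts:
        return AngiogenicMetrics(timepoint_label="truth", flags=("undefined_ar",))

    r_vals = cps[:, 1]
    straight = np.ptp(r_vals) < 1e-9
    u_lo = min(cps[0, 0], min(s.base_point[0] for s in sprouts)) - 400.0
    u_hi = max(cps[-1, 0], max(s.base_point[0] for s in sprouts)) + 400.0
    poly = _monolayer_polyline_region(cps, (u_lo, u_hi))

    M_c = J_c = 0.0
    cyto_u: List[np.ndarray] = []
    cyto_w: List[np.ndarray] = []
    M_h = J_h = 0.0
    hoechst_u: List[np.ndarray] = []
    hoechst_w: List[np.ndarray] = []

    for spec in sprouts:
        u_b, r_b = spec.base_point
        if r_b is None:
            r_b = float(MonolayerCurve(cps).spline()(u_b))
        phi = math.radians(spec.direction_deg)
        normal_case = straight and abs(spec.direction_deg) < 1e-12
        if normal_case:
            M, J = cylinder_integrals(
                spec.cyto_intensity, spec.radius_um, spec.length_um, offset_um
            )
            M_c += M
            J_c += J
            if M > 0:
                # u-offset distribution across the circular section: E|du|
                # about the sprout base is 4 rho / (3 pi); represent the
                # section by dense in-plane offsets for the lateral moment
                nr, na = 24, 48
                rr = (np.arange(nr) + 0.5) * spec.radius_um / nr
                aa = (np.arange(na) + 0.5) * 2 * math.pi / na
                RR, AA = np.meshgrid(rr, aa, indexing="ij")
                du = (RR * np.cos(AA)).ravel()
                w = (RR * (spec.radius_um / nr) * (2 * math.pi / na)).ravel()
                w = w / w.sum() * M
                cyto_u.append(u_b + du)
                cyto_w.append(w)
        else:
            M, J, uu, ww = _cylinder_quadrature(spec, poly, offset_um, r_b)
            M_c += M
            J_c += J
            cyto_u.append(uu)
            cyto_w.append(ww)

        if spec.n_nuclei > 0:
            axis = np.array([math.sin(phi), math.cos(phi)])
            az, aperp, apar = spec.nucleus_semiaxes_um
            vol = 4.0 / 3.0 * math.pi * az * aperp * apar
            support = math.hypot(apar * math.cos(phi), aperp * math.sin(phi))
            pts, wts = _nucleus_ellipsoid_samples(spec)
            for t_i in spec.nucleus_axial_positions():
                center = np.array([u_b, r_b]) + t_i * axis
                if straight:
                    r_center = center[1] - r_vals[0]
                else:
                    dc, _ = signed_distance_to_polyline(center[None, :], poly)
                    r_center = abs(float(dc[0]))
                tau = (offset_um - r_center) / support
                frac = float(_sphere_cap_fraction(np.array(tau)))
                mom = float(_sphere_cap_moment(np.array(tau)))
                M_h += spec.nucleus_intensity * vol * frac
                J_h += spec.nucleus_intensity * vol * (
                    r_center * frac + support * mom
                )
                if frac > 0:
                    # lateral samples for the aspect ratio
                    u_s = (
                        center[0]
                        + pts[:, 0] * math.sin(phi)
                        + pts[:, 1] * math.cos(phi)
                    )
                    r_s = (
                        r_center
                        + pts[:, 0] * math.cos(phi)
                        - pts[:, 1] * math.sin(phi)
                    )
                    sel = r_s >= offset_um
                    hoechst_u.append(u_s[sel])
                    hoechst_w.append(spec.nucleus_intensity * wts[sel])

    def _ar(us: List[np.ndarray], ws: List[np.ndarray], M: float, J: float) -> float:
        if M <= 0 or not us:
            return float("nan")
        u = np.concatenate(us)
        w = np.concatenate(ws)
        ubar = float((w * u).sum() / w.sum())
        lateral = float((w * np.abs(u - ubar)).sum() / w.sum())
        if lateral <= 0:
            return float("nan")
        return (J / M) / lateral

    flags: Tuple[str, ...] = ()
    if M_c <= 0 and M_h <= 0:
        flags = ("undefined_ar",)
    return AngiogenicMetrics(
        M_cyto=M_c,
        J_cyto=J_c,
        AR_cyto=_ar(cyto_u, cyto_w, M_c, J_c),
        M_hoechst=M_h,
        J_hoechst=J_h,
        AR_hoechst=_ar(hoechst_u, hoechst_w, M_h, J_h),
        timepoint_label="truth",
        flags=flags,
    )


# ---------------------------------------------------------------------------
# rendering


def _rot_matrix(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


class _SceneTransform:
    """Rigid map from the device frame to the image frame (rotation about the
    image center followed by a translation)."""

    def __init__(
        self, rotation_deg: float, shift_um: Tuple[float, float], center: np.ndarray
    ):
        self.R = _rot_matrix(rotation_deg)
        self.shift = np.asarray(shift_um, dtype=float)  # (dx, dy)
        self.center = center

    def forward(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (pts - self.center) @ self.R.T + self.center + self.shift

    def inverse_xy(self, X: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        dx = X - self.center[0] - self.shift[0]
        dy = Y - self.center[1] - self.shift[1]
        R = self.R
        xd = R[0, 0] * dx + R[1, 0] * dy + self.center[0]
        yd = R[0, 1] * dx + R[1, 1] * dy + self.center[1]
        return xd, yd


def _device_post_polygons(geom: DeviceGeometry, margin: float) -> List[np.ndarray]:
    """Trapezoidal posts in the device frame: wide base flush with the gel
    boundary, converging into the gel (stiffening caged interface)."""
    P = geom.period_um
    y0 = margin
    y1 = margin + geom.gel_width_um
    b = geom.post_base_width_um / 2.0
    tw = geom.post_top_width_um / 2.0
    d = geom.post_depth_um
    polys = []
    for xc in (0.0, P):
        polys.append(
            np.array(
                [[xc - b, y0], [xc + b, y0], [xc + tw, y0 + d], [xc - tw, y0 + d]]
            )
        )
        polys.append(
            np.array(
                [[xc - b, y1], [xc + b, y1], [xc + tw, y1 - d], [xc - tw, y1 - d]]
            )
        )
    return polys


def _points_in_convex_poly(x: np.ndarray, y: np.ndarray, poly: np.ndarray) -> np.ndarray:
    inside = np.ones(x.shape, dtype=bool)
    n = len(poly)
    area2 = sum(
        poly[i, 0] * poly[(i + 1) % n, 1] - poly[(i + 1) % n, 0] * poly[i, 1]
        for i in range(n)
    )
    ccw = area2 >= 0
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        inside &= (cross >= 0) if ccw else (cross <= 0)
    return inside


def render_stack(
    geom: DeviceGeometry,
    monolayer_control_points: np.ndarray,
    sprouts: Sequence[SproutSpec] = (),
    noise: Optional[NoiseSpec] = None,
    *,
    margin_um: float = 60.0,
    monolayer_intensity: float = 1.0,
    monolayer_thickness_um: float = 12.0,
    blur_sigma_um: float = 2.0,
    shift_um: Tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    truth_offset_um: float = 10.0,
    timepoint_label: str = "0hr",
    device_id: str = "D0",
    region_index: int = 0,
) -> Tuple[ImageStack, GroundTruth]:
    """Render one gel growth region as a 4-channel stack plus ground truth.

    The scene is laid out in the device frame (one post period along x, the
    gel strip plus a channel margin along y) and rasterized through an
    optional rigid transform (``shift_um``, ``rotation_deg`` about the image
    center) emulating stage repositioning between imaging days.  Structures
    are rendered with subvoxel supersampling so voxel sums converge to the
    analytic integrals, and fluorescence channels receive a volume-normalized
    Gaussian blur (sigma in um) emulating the optics without changing the
    integral metrics.
    """
    cps = np.asarray(monolayer_control_points, dtype=float)
    if cps.shape != (4, 2):
        raise ValueError("monolayer_control_points: expected (4, 2) (u, r) um")
    if np.any(cps[:, 1] < 0) or np.any(cps[:, 1] > geom.gel_width_um):
        raise ValueError("monolayer control points must lie within the gel strip")

    P = geom.period_um
    dz, dy, dx = geom.voxel_size_um
    nx = int(round(P / dx))
    ny = int(round((geom.gel_width_um + 2 * margin_um) / dy))
    nz = geom.n_z_sections
    width = nx * dx
    height = ny * dy
    y0 = margin_um
    y1 = margin_um + geom.gel_width_um
    center = np.array([width / 2.0, height / 2.0])
    T = _SceneTransform(rotation_deg, shift_um, center)
    posts = _device_post_polygons(geom, margin_um)

    ml_curve = MonolayerCurve(np.column_stack([cps[:, 0], y0 + cps[:, 1]]))
    ml_poly = ml_curve.polyline(step_um=min(dx, dy) / 2.0, x_range=(-2 * dx, width + 2 * dx))

    # --- 2D fields at 2x supersampling -------------------------------------
    ss = 2
    xs = (np.arange(nx * ss) + 0.5) * dx / ss
    ys = (np.arange(ny * ss) + 0.5) * dy / ss
    X, Y = np.meshgrid(xs, ys)
    Xd, Yd = T.inverse_xy(X, Y)

    refl = np.where((Yd >= y0) & (Yd <= y1), GEL_REFLECTANCE, PDMS_REFLECTANCE)
    post_mask = np.zeros(X.shape, dtype=bool)
    for poly in posts:
        post_mask |= _points_in_convex_poly(Xd, Yd, poly)
    refl[post_mask] = PDMS_REFLECTANCE

    from scipy.spatial import cKDTree

    band = np.zeros(X.shape)
    if monolayer_intensity > 0:
        tree = cKDTree(ml_poly)
        dist, _ = tree.query(np.column_stack([Xd.ravel(), Yd.ravel()]))
        band = (dist.reshape(X.shape) <= monolayer_thickness_um / 2.0).astype(float)
        band *= monolayer_intensity

    def _down(a: np.ndarray) -> np.ndarray:
        return a.reshape(ny, ss, nx, ss).mean(axis=(1, 3))

    refl2d = _down(refl)
    post2d = _down(post_mask.astype(float))
    band2d = _down(band)

    # --- 3D structures ------------------------------------------------------
    cyto = np.broadcast_to(band2d, (nz, ny, nx)).copy()
    nuc = np.zeros((nz, ny, nx))
    z_mid = nz * dz / 2.0
    clipped: List[int] = []
    ml_spline = ml_curve.spline()

    for si, spec in enumerate(sprouts):
        u_b, r_b = spec.base_point
        if r_b is None:
            base_y = float(ml_spline(u_b))
        else:
            base_y = y0 + r_b
        phi = math.radians(spec.direction_deg)
        axis2 = np.array([math.sin(phi), math.cos(phi)])
        base = np.array([u_b, base_y])
        tip = base + spec.length_um * axis2
        if (
            tip[1] + spec.radius_um > y1
            or tip[1] - spec.radius_um < y0
            or min(base[0], tip[0]) - spec.radius_um < 0
            or max(base[0], tip[0]) + spec.radius_um > width
        ):
            warnings.warn(
                f"sprout {si} extends outside the gel region; rendering clipped"
            )
            clipped.append(si)
        _raster_cylinder(
            cyto, T, base, axis2, spec.length_um, spec.radius_um,
            spec.cyto_intensity, z_mid, (dz, dy, dx),
        )
        if spec.n_nuclei > 0:
            for t_i in spec.nucleus_axial_positions():
                c2 = base + t_i * axis2
                _raster_ellipsoid(
                    nuc, T, c2, phi, spec.nucleus_semiaxes_um,
                    spec.nucleus_intensity, z_mid, (dz, dy, dx),
                )

    if blur_sigma_um > 0:
        sigmas = tuple(blur_sigma_um / v for v in (dz, dy, dx))
        cyto = ndimage.gaussian_filter(cyto, sigma=sigmas, mode="constant")
        nuc = ndimage.gaussian_filter(nuc, sigma=sigmas, mode="constant")

    peak = max(monolayer_intensity, max((s.cyto_intensity for s in sprouts), default=0.0), 1e-9)
    occupancy = np.clip(cyto / peak, 0.0, 1.0)
    # transmitted light is attenuated by cell mass; PDMS is transparent
    trans = np.clip(1.0 - 0.5 * occupancy, 0.0, None)
    refl3d = np.broadcast_to(refl2d, (nz, ny, nx)).copy()

    channels = {
        "cyto": cyto,
        "hoechst": nuc,
        "reflectance": refl3d,
        "transmitted": trans,
    }
    if noise is not None and (noise.background_sd > 0 or noise.background_mean != 0):
        rng = np.random.default_rng(noise.seed)
        for name in ("cyto", "hoechst", "reflectance", "transmitted"):
            channels[name] = channels[name] + rng.normal(
                noise.background_mean, noise.background_sd, (nz, ny, nx)
            )
    channels = {k: np.ascontiguousarray(v, dtype=np.float32) for k, v in channels.items()}

    stack = ImageStack(
        channels=channels,
        voxel_size_um=(dz, dy, dx),
        timepoint_label=timepoint_label,
        device_id=device_id,
        region_index=region_index,
    )

    # --- ground truth in the image frame ------------------------------------
    lines = []
    for yl in (y0, y1):
        p = T.forward(np.array([[0.0, yl], [width, yl]]))
        ang = math.degrees(math.atan2(p[1, 1] - p[0, 1], p[1, 0] - p[0, 0]))
        frac = (width / 2.0 - p[0, 0]) / (p[1, 0] - p[0, 0])
        off = p[0, 1] + frac * (p[1, 1] - p[0, 1])
        lines.append((float(off), float(ang)))
    truth = GroundTruth(
        boundary_lines=lines,
        x_mid_um=width / 2.0,
        post_polygons=[T.forward(p) for p in posts],
        monolayer_control_points=T.forward(ml_curve.control_points),
        monolayer_control_points_region=cps.copy(),
        metrics_true=ground_truth_metrics(sprouts, cps, truth_offset_um),
        offset_um=truth_offset_um,
        gel_width_um=geom.gel_width_um,
        period_um=P,
        margin_um=margin_um,
        clipped_sprouts=tuple(clipped),
    )
    return stack, truth


def _raster_cylinder(
    out: np.ndarray,
    T: _SceneTransform,
    base: np.ndarray,
    axis2: np.ndarray,
    length: float,
    radius: float,
    intensity: float,
    z_mid: float,
    voxel: Tuple[float, float, float],
) -> None:
    """Add a flat-capped cylinder (axis in the xy-plane at depth z_mid) with
    subvoxel supersampling; the voxel sum converges to intensity x volume."""
    if intensity <= 0 or length <= 0:
        return
    dz, dy, dx = voxel
    nz, ny, nx = out.shape
    tip = base + length * axis2
    corners_dev = np.array(
        [
            base + radius * np.array([1, 1]),
            base - radius * np.array([1, 1]),
            tip + radius * np.array([1, 1]),
            tip - radius * np.array([1, 1]),
        ]
    )
    corners_img = T.forward(corners_dev)
    pad = radius + max(dx, dy)
    ix0 = max(int((corners_img[:, 0].min() - pad) / dx), 0)
    ix1 = min(int((corners_img[:, 0].max() + pad) / dx) + 1, nx)
    iy0 = max(int((corners_img[:, 1].min() - pad) / dy), 0)
    iy1 = min(int((corners_img[:, 1].max() + pad) / dy) + 1, ny)
    iz0 = max(int((z_mid - radius) / dz - 1), 0)
    iz1 = min(int((z_mid + radius) / dz) + 2, nz)
    if ix1 <= ix0 or iy1 <= iy0 or iz1 <= iz0:
        return
    sz, sy, sx = 8, 3, 3
    zz = (np.arange(iz0 * sz, iz1 * sz) + 0.5) * dz / sz
    yy = (np.arange(iy0 * sy, iy1 * sy) + 0.5) * dy / sy
    xx = (np.arange(ix0 * sx, ix1 * sx) + 0.5) * dx / sx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    Xd, Yd = T.inverse_xy(X, Y)
    rel_u = Xd - base[0]
    rel_v = Yd - base[1]
    t = rel_u * axis2[0] + rel_v * axis2[1]
    perp = rel_u * -axis2[1] + rel_v * axis2[0]
    rad2 = perp**2 + (Z - z_mid) ** 2
    inside = (t >= 0) & (t <= length) & (rad2 <= radius**2)
    frac = inside.reshape(
        iz1 - iz0, sz, iy1 - iy0, sy, ix1 - ix0, sx
    ).mean(axis=(1, 3, 5))
    out[iz0:iz1, iy0:iy1, ix0:ix1] += intensity * frac


def _raster_ellipsoid(
    out: np.ndarray,
    T: _SceneTransform,
    center2: np.ndarray,
    phi: float,
    semiaxes: Tuple[float, float, float],
    intensity: float,
    z_mid: float,
    voxel: Tuple[float, float, float],
) -> None:
    az, aperp, apar = semiaxes
    if intensity <= 0:
        return
    dz, dy, dx = voxel
    nz, ny, nx = out.shape
    r_xy = max(apar, aperp)
    c_img = T.forward(center2[None, :])[0]
    ix0 = max(int((c_img[0] - r_xy - dx) / dx), 0)
    ix1 = min(int((c_img[0] + r_xy + dx) / dx) + 1, nx)
    iy0 = max(int((c_img[1] - r_xy - dy) / dy), 0)
    iy1 = min(int((c_img[1] + r_xy + dy) / dy) + 1, ny)
    iz0 = max(int((z_mid - az) / dz - 1), 0)
    iz1 = min(int((z_mid + az) / dz) + 2, nz)
    if ix1 <= ix0 or iy1 <= iy0 or iz1 <= iz0:
        return
    sz, sy, sx = 8, 4, 4
    zz = (np.arange(iz0 * sz, iz1 * sz) + 0.5) * dz / sz
    yy = (np.arange(iy0 * sy, iy1 * sy) + 0.5) * dy / sy
    xx = (np.arange(ix0 * sx, ix1 * sx) + 0.5) * dx / sx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    Xd, Yd = T.inverse_xy(X, Y)
    axis2 = np.array([math.sin(phi), math.cos(phi)])
    rel_u = Xd - center2[0]
    rel_v = Yd - center2[1]
    tpar = rel_u * axis2[0] + rel_v * axis2[1]
    tperp = rel_u * -axis2[1] + rel_v * axis2[0]
    inside = (
        (tpar / apar) ** 2 + (tperp / aperp) ** 2 + ((Z - z_mid) / az) ** 2
    ) <= 1.0
    frac = inside.reshape(
        iz1 - iz0, sz, iy1 - iy0, sy, ix1 - ix0, sx
    ).mean(axis=(1, 3, 5))
    out[iz0:iz1, iy0:iy1, ix0:ix1] += intensity * frac
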