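"""Chemoattractant transport in the ensemble device.

Steady advection-diffusion of a growth factor (e.g. 40 kDa VEGF analog,
D ~ 5e-11 m^2/s in collagen and in medium) on a simplified 2D plan view of
the device: two media channels running along x, the gel strip between them,
and trapezoidal post footprints blocking the gel edges.  Channel flow is
plug advection along x; the gel is purely diffusive (growth-factor binding
is neglected).  Boundary conditions: Dirichlet source/sink at the channel
inlets, pure convective outflow at the outlets, no-flux elsewhere, and an
optional concentration sink at the gel-filling ports at both ends of the
strip (the large gel mass there acts as a sink).

The module also provides the device-design calculators: the Peclet number
(axial and lateral forms) and the Young-Laplace containment pressure of the
gel-air interface caged by the posts.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .phantom import DeviceGeometry


@dataclasses.dataclass(frozen=True)
class TransportConfig:
    """Inputs of the steady transport solve.

    ``flow_rate_ul_min`` is the volumetric flow per channel; 0 (or None)
    means the idealized fixed-concentration limit, where the gel strip edges
    are held at the channel concentrations and only diffusion acts.
    """

    geometry: DeviceGeometry
    D_gel_m2_s: float = 5e-11
    D_med_m2_s: float = 5e-11
    flow_rate_ul_min: Optional[float] = 1.0
    C_source: float = 40.0
    C_sink: float = 20.0
    gel_port_sink: bool = False
    channel_height_um: float = 160.0
    dx_um: float = 25.0
    dy_um: float = 25.0
    include_posts: bool = True

    def __post_init__(self) -> None:
        if self.D_gel_m2_s <= 0 or self.D_med_m2_s <= 0:
            raise ValueError("diffusivities must be > 0")
        if self.flow_rate_ul_min is not None and self.flow_rate_ul_min < 0:
            raise ValueError("flow_rate_ul_min: must be >= 0 or None")
        if self.dx_um <= 0 or self.dy_um <= 0:
            raise ValueError("grid spacings must be > 0")
        if self.include_posts and self.dx_um > self.geometry.post_spacing_um / 4:
            raise ValueError(
                "dx_um: need >= 4 nodes across each gel gap "
                f"(post spacing {self.geometry.post_spacing_um} um)"
            )

    @property
    def channel_velocity_um_s(self) -> float:
        """Mean plug-flow velocity in each channel (um/s)."""
        if not self.flow_rate_ul_min:
            return 0.0
        q_m3_s = self.flow_rate_ul_min * 1e-9 / 60.0
        area_m2 = (self.geometry.channel_width_um * 1e-6) * (
            self.channel_height_um * 1e-6
        )
        return q_m3_s / area_m2 * 1e6


@dataclasses.dataclass
class ConcentrationField:
    """Steady concentration on the plan-view grid (NaN inside posts)."""

    x_um: np.ndarray
    y_um: np.ndarray
    C: np.ndarray  # (ny, nx)
    solid: np.ndarray  # (ny, nx) bool
    gel_rows: Tuple[int, int]  # [row0, row1) slice of the gel strip
    region_x_spans: List[Tuple[float, float]]
    config: TransportConfig
    residual: float = 0.0


@dataclasses.dataclass(frozen=True)
class MeniscusSpec:
    """Gel-air interface caged between posts during filling.

    ``Rx_um`` is set by the post spacing and contact angle, ``Rz_um`` by the
    channel height; ``None`` means flat (no curvature contribution).
    """

    gamma_n_m: float = 0.07
    Rx_um: Optional[float] = None
    Rz_um: Optional[float] = None
    contact_angle_deg: float = 120.0
    post_spacing_um: float = 100.0
    channel_height_um: float = 160.0

    def __post_init__(self) -> None:
        if self.gamma_n_m <= 0:
            raise ValueError("gamma_n_m: must be > 0")
        for name in ("Rx_um", "Rz_um"):
            r = getattr(self, name)
            if r is not None and not (r > 0 or math.isinf(r)):
                raise ValueError(f"{name}: radius must be > 0, infinite, or None")


def laplace_pressure(spec: MeniscusSpec) -> float:
    """Young-Laplace pressure differential sustained by the interface (Pa).

    dP = gamma (1/Rx + 1/Rz); a flat direction (None or infinite radius)
    contributes nothing.
    """
    total = 0.0
    for r_um in (spec.Rx_um, spec.Rz_um):
        if r_um is None or math.isinf(r_um):
            continue
        total += 1.0 / (r_um * 1e-6)
    return spec.gamma_n_m * total


def supplement_angle(contact_angle_deg: float) -> float:
    """Post base angle supplementary to the gel/PDMS contact angle."""
    if not 0 < contact_angle_deg < 180:
        raise ValueError("contact_angle_deg: must be in (0, 180)")
    return 180.0 - contact_angle_deg


def peclet(u_m_s: float, h_m: float, L_m: float, D_m2_s: float) -> float:
    """Lateral Peclet number Pe = u (h/L) h / D.

    Accounts for transport in both the axial (channel length L) and lateral
    (channel width h) directions.
    """
    if u_m_s <= 0 or h_m <= 0 or L_m <= 0 or D_m2_s <= 0:
        raise ValueError("all Peclet inputs must be > 0")
    return u_m_s * (h_m / L_m) * h_m / D_m2_s


def peclet_axial(u_m_s: float, L_m: float, D_m2_s: float) -> float:
    """Axial Peclet number Pe = u L / D (convection vs axial diffusion)."""
    if u_m_s <= 0 or L_m <= 0 or D_m2_s <= 0:
        raise ValueError("all Peclet inputs must be > 0")
    return u_m_s * L_m / D_m2_s


# ---------------------------------------------------------------------------
# finite-difference solver


def _post_solid_mask(
    config: TransportConfig, xs: np.ndarray, ys: np.ndarray, gel0_um: float
) -> np.ndarray:
    geom = config.geometry
    X, Y = np.meshgrid(xs, ys)
    solid = np.zeros(X.shape, dtype=bool)
    if not config.include_posts:
        return solid
    P = geom.period_um
    half_b = geom.post_base_width_um / 2.0
    half_t = geom.post_top_width_um / 2.0
    d = geom.post_depth_um
    gel1_um = gel0_um + geom.gel_width_um
    centers = P / 2.0 + np.arange(geom.n_regions + 1) * P
    for xc in centers:
        rel = np.abs(X - xc)
        # lower edge trapezoid: width tapers from base to top over depth d
        depth_lo = Y - gel0_um
        with np.errstate(invalid="ignore"):
            w_lo = half_b + (half_t - half_b) * depth_lo / d
        solid |= (depth_lo >= 0) & (depth_lo <= d) & (rel <= w_lo)
        depth_hi = gel1_um - Y
        w_hi = half_b + (half_t - half_b) * depth_hi / d
        solid |= (depth_hi >= 0) & (depth_hi <= d) & (rel <= w_hi)
    return solid


def solve_steady(config: TransportConfig) -> ConcentrationField:
    """Solve the steady advection-diffusion problem on the plan-view grid.

    Finite volumes with harmonic-mean interface diffusivities and first-order
    upwind advection in the channels; the resulting M-matrix guarantees the
    discrete maximum principle (C_sink <= C <= C_source everywhere).  The
    sparse system is solved directly; the relative residual is recorded.
    """
    geom = config.geometry
    dx, dy = config.dx_um, config.dy_um
    P = geom.period_um
    L = geom.n_regions * P + P  # half-period margin at each end
    region_x = [(P / 2 + i * P, P / 2 + (i + 1) * P) for i in range(geom.n_regions)]

    fixed_edges = not config.flow_rate_ul_min  # 0 or None
    ny_gel = max(int(round(geom.gel_width_um / dy)), 4)
    if fixed_edges:
        ny_ch = 1  # single Dirichlet row per side
    else:
        ny_ch = max(int(round(geom.channel_width_um / dy)), 2)
    ny = 2 * ny_ch + ny_gel
    nx = max(int(round(L / dx)), 8)
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    gel_rows = (ny_ch, ny_ch + ny_gel)
    gel0_um = ny_ch * dy

    D_gel = config.D_gel_m2_s * 1e12  # um^2/s
    D_med = config.D_med_m2_s * 1e12
    D_cell = np.full((ny, nx), D_gel)
    D_cell[: gel_rows[0]] = D_med
    D_cell[gel_rows[1]:] = D_med

    solid = np.zeros((ny, nx), dtype=bool)
    solid[gel_rows[0]: gel_rows[1]] = _post_solid_mask(
        config, xs, ys[gel_rows[0]: gel_rows[1]], gel0_um
    )

    u = np.zeros(ny)
    if not fixed_edges:
        u[: gel_rows[0]] = config.channel_velocity_um_s
        u[gel_rows[1]:] = config.channel_velocity_um_s

    # Dirichlet cells: value or None
    dirichlet = np.full((ny, nx), np.nan)
    if fixed_edges:
        dirichlet[: gel_rows[0], :] = config.C_sink
        dirichlet[gel_rows[1]:, :] = config.C_source
    else:
        dirichlet[: gel_rows[0], 0] = config.C_sink
        dirichlet[gel_rows[1]:, 0] = config.C_source
    if config.gel_port_sink:
        dirichlet[gel_rows[0]: gel_rows[1], 0] = config.C_sink
        dirichlet[gel_rows[0]: gel_rows[1], -1] = config.C_sink

    idx = -np.ones((ny, nx), dtype=int)
    fluid = ~solid
    idx[fluid] = np.arange(fluid.sum())
    n = int(fluid.sum())
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    b = np.zeros(n)

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for j in range(ny):
        for i in range(nx):
            if solid[j, i]:
                continue
            k = idx[j, i]
            if not np.isnan(dirichlet[j, i]):
                add(k, k, 1.0)
                b[k] = dirichlet[j, i]
                continue
            diag = 0.0
            # diffusion to the four neighbors
            for (jj, ii, face, dist) in (
                (j, i - 1, dy, dx),
                (j, i + 1, dy, dx),
                (j - 1, i, dx, dy),
                (j + 1, i, dx, dy),
            ):
                if not (0 <= jj < ny and 0 <= ii < nx) or solid[jj, ii]:
                    continue
                Dh = 2.0 * D_cell[j, i] * D_cell[jj, ii] / (
                    D_cell[j, i] + D_cell[jj, ii]
                )
                g = Dh * face / dist
                diag += g
                add(k, idx[jj, ii], -g)
            # upwind advection along +x in channel rows
            if u[j] > 0:
                F = u[j] * dy
                diag += F
                if i - 1 >= 0 and not solid[j, i - 1]:
                    add(k, idx[j, i - 1], -F)
                # at the outlet (i == nx-1) the out-flux u*C is the pure
                # convective outflow condition; no extra term needed
            add(k, k, diag)

    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    c_flat = spsolve(A, b)
    resid = float(
        np.linalg.norm(A @ c_flat - b) / max(np.linalg.norm(b), 1e-300)
    )
    C = np.full((ny, nx), np.nan)
    C[fluid] = c_flat
    return ConcentrationField(
        x_um=xs,
        y_um=ys,
        C=C,
        solid=solid,
        gel_rows=gel_rows,
        region_x_spans=region_x,
        config=config,
        residual=resid,
    )


def cross_gel_profile(field: ConcentrationField, x_um: float) -> Tuple[np.ndarray, np.ndarray]:
    """Concentration across the gel at the column nearest ``x_um``."""
    i = int(np.argmin(np.abs(field.x_um - x_um)))
    r0, r1 = field.gel_rows
    return field.y_um[r0:r1], field.C[r0:r1, i]


def region_gradients(field: ConcentrationField, mode: str = "mid") -> np.ndarray:
    """Cross-gel gradient steepness per growth region.

    ``mode='mid'`` evaluates |dC/dy| at the mid-gel row (grid-robust, used
    for uniformity and convergence checks); ``mode='max'`` takes the maximum
    across the gel depth (sensitive to the local steepening near the
    gel-filling ports).  Both are averaged over the region's columns and
    exclude the post-occupied edge bands.
    """
    if mode not in ("mid", "max"):
        raise ValueError("mode: 'mid' or 'max'")
    r0, r1 = field.gel_rows
    pd = field.config.geometry.post_depth_um
    skip = int(math.ceil(pd / field.config.dy_um)) + 1
    rows = slice(r0 + skip, r1 - skip)
    out = []
    for (xa, xb) in field.region_x_spans:
        cols = np.where((field.x_um >= xa) & (field.x_um < xb))[0]
        g = np.gradient(field.C[rows, :][:, cols], field.config.dy_um, axis=0)
        if mode == "max":
            out.append(float(np.nanmax(np.abs(g), axis=0).mean()))
        else:
            mid = g.shape[0] // 2
            out.append(float(np.abs(g[mid]).mean()))
    return np.array(out)


def axial_uniformity(field: ConcentrationField) -> float:
    """Relative change of the cross-gel gradient along the device.

    Compares the first and last interior regions (the outermost two regions
    on each side are excluded: they are perturbed by the gel-filling ports).
    0 means perfectly uniform gradients along the device length.
    """
    g = region_gradients(field)
    interior = g[2:-2] if len(g) > 4 else g
    mean = float(np.mean(np.abs(interior)))
    if mean == 0:
        return 0.0
    return float(abs(interior[0] - interior[-1]) / mean)


def flow_rate_sweep(
    config: TransportConfig, flow_rates_ul_min: Tuple[float, ...]
) -> List[Tuple[float, float]]:
    """Axial-uniformity statistic for a set of channel flow rates."""
    out = []
    for q in flow_rates_ul_min:
        cfg = dataclasses.replace(config, flow_rate_ul_min=q)
        out.append((q, axial_uniformity(solve_steady(cfg))))
    return out
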