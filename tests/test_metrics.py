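"""Invasion metrics: integration region, distance field, M, J, AR and
differentials, validated against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

import angioquant as aq
import angioquant.metrics as met
import angioquant.preprocess as pp
from angioquant.geometry import GelRegion
from angioquant.monolayer import MonolayerCurve

from _util import SMALL_GEOM, default_sprout, region_from_truth, straight_cps


def synthetic_region(ny=100, nx=60, nz=4, voxel=(1.0, 1.0, 1.0), y0=10.0, y1=90.0):
    """A bare rectangular gel strip without posts (1 um voxels by default)."""
    return GelRegion(
        boundary_lines=[(y0, 0.0), (y1, 0.0)],
        x_mid_um=nx * voxel[2] / 2,
        post_polygons=[],
        region_index=0,
        image_shape=(nz, ny, nx),
        voxel_size_um=voxel,
    )


def straight_curve(y, nx=60):
    return MonolayerCurve(
        np.array([[0.0, y], [nx / 3, y], [2 * nx / 3, y], [float(nx), y]])
    )


class TestIntegrationRegion:
    def test_zero_offset_at_gel_edge_recovers_full_strip(self):
        region = synthetic_region()
        mask = met.integration_region(region, straight_curve(10.0), 0.0)
        area = mask.mask2d.sum()  # pixels of 1 um^2
        assert area == pytest.approx(80 * 60, abs=2 * 60)  # within 1 px layer

    def test_offset_shrinks_area_by_offset_band(self):
        region = synthetic_region()
        mask = met.integration_region(region, straight_curve(10.0), 10.0)
        assert mask.mask2d.sum() == pytest.approx(70 * 60, abs=2 * 60)

    def test_offset_beyond_gel_width_is_error(self):
        region = synthetic_region()
        with pytest.raises(ValueError, match="empty"):
            met.integration_region(region, straight_curve(10.0), 90.0)

    def test_post_polygons_are_excluded(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        region = region_from_truth(truth, stack)
        curve = MonolayerCurve(truth.monolayer_control_points)
        mask = met.integration_region(region, curve, 0.0)
        dz, dy, dx = stack.voxel_size_um
        ys = (np.arange(mask.mask2d.shape[0]) + 0.5) * dy
        xs = (np.arange(mask.mask2d.shape[1]) + 0.5) * dx
        # a point well inside an upper post footprint must be excluded
        poly = truth.post_polygons[1]  # upper post at x = 0
        probe_x = np.argmin(np.abs(xs - 8.0))
        probe_y = np.argmin(np.abs(ys - (truth.boundary_lines[1][0] - 5.0)))
        assert not mask.mask2d[probe_y, probe_x]


class TestDistanceField:
    def test_straight_curve_distance_is_vertical_offset(self):
        region = synthetic_region()
        field = met.distance_field(straight_curve(10.0), region)
        iy = 35  # pixel center y = 35.5 um -> r = 25.5
        assert field.r_um[iy, 30] == pytest.approx(25.5, abs=1e-6)

    def test_rigid_translation_invariance(self):
        r1 = synthetic_region()
        f1 = met.distance_field(straight_curve(10.0), r1)
        r2 = synthetic_region(y0=20.0, y1=100.0, ny=110)
        f2 = met.distance_field(straight_curve(20.0), r2)
        assert f2.r_um[50, 30] == pytest.approx(f1.r_um[40, 30], abs=1e-9)

    def test_sinusoidal_curve_against_brute_force_oracle(self):
        region = synthetic_region()
        cp = np.array([[0.0, 20.0], [20.0, 35.0], [40.0, 15.0], [60.0, 30.0]])
        curve = MonolayerCurve(cp)
        field = met.distance_field(curve, region)
        dense = curve.polyline(step_um=0.01, x_range=(0.0, 60.0))
        rng = np.random.default_rng(0)
        for _ in range(25):
            iy, ix = rng.integers(45, 95), rng.integers(5, 55)
            p = np.array([ix + 0.5, iy + 0.5])
            brute = np.min(np.hypot(*(dense - p).T))
            assert abs(abs(field.r_um[iy, ix]) - brute) < 0.1


class TestIntegralMetrics:
    def test_uniform_cube_total_integral(self):
        region = synthetic_region(nz=10)
        mask = met.integration_region(region, straight_curve(10.0), 0.0)
        sig = np.zeros((10, 100, 60))
        sig[:, 40:50, 20:30] = 1.0  # 10x10x10 voxels of 1 um^3
        assert met.total_integral(sig, mask) == pytest.approx(1000.0)

    def test_point_blob_first_moment(self):
        region = synthetic_region(nz=2)
        curve = straight_curve(10.0)
        field = met.distance_field(curve, region)
        mask = met.integration_region(region, curve, 0.0, field=field)
        sig = np.zeros((2, 100, 60))
        iy = 50  # pixel center y = 50.5 um -> r = 40.5 um
        sig[:, iy, 25] = 2.5
        M = met.total_integral(sig, mask)
        J = met.first_moment(sig, mask, field)
        assert J == pytest.approx(40.5 * M, rel=1e-6)

    def test_uniform_rod_centroid_at_35_um(self):
        # rod from r = 10 to 60 um: J / M = 35 um (analytic centroid)
        region = synthetic_region(nz=2)
        curve = straight_curve(10.0)
        field = met.distance_field(curve, region)
        mask = met.integration_region(region, curve, 0.0, field=field)
        sig = np.zeros((2, 100, 60))
        ys = (np.arange(100) + 0.5)
        rows = (ys - 10.0 >= 10.0) & (ys - 10.0 <= 60.0)
        sig[:, rows, 30] = 1.0
        M = met.total_integral(sig, mask)
        J = met.first_moment(sig, mask, field)
        assert J / M == pytest.approx(35.0, abs=0.5)

    def test_additivity_over_disjoint_blobs(self):
        region = synthetic_region(nz=2)
        mask = met.integration_region(region, straight_curve(10.0), 0.0)
        a = np.zeros((2, 100, 60))
        a[:, 30:35, 10:15] = 1.0
        b = np.zeros((2, 100, 60))
        b[:, 60:70, 40:50] = 0.7
        Ma = met.total_integral(a, mask)
        Mb = met.total_integral(b, mask)
        assert met.total_integral(a + b, mask) == pytest.approx(Ma + Mb, rel=1e-9)


class TestAspectRatio:
    def _disc_setup(self, r0=60.0, radius=6.0):
        region = synthetic_region(ny=120, nx=80)
        curve = straight_curve(10.0, nx=80)
        field = met.distance_field(curve, region)
        mask = met.integration_region(region, curve, 0.0, field=field)
        sig = np.zeros((4, 120, 80))
        ys, xs = np.meshgrid(
            np.arange(120) + 0.5, np.arange(80) + 0.5, indexing="ij"
        )
        disc = (ys - (10.0 + r0)) ** 2 + (xs - 40.0) ** 2 <= radius**2
        sig[:, disc] = 1.0
        return sig, mask, field

    def test_isotropic_disc_matches_monte_carlo_oracle(self):
        r0, radius = 60.0, 6.0
        sig, mask, field = self._disc_setup(r0, radius)
        ar, flags = met.aspect_ratio(sig, mask, field)
        # oracle: mean |du| over a uniform disc, by Monte Carlo
        rng = np.random.default_rng(42)
        pts = rng.uniform(-radius, radius, (200000, 2))
        pts = pts[(pts**2).sum(axis=1) <= radius**2]
        lateral = np.abs(pts[:, 0]).mean()
        assert ar == pytest.approx(r0 / lateral, rel=0.05)

    def test_mirror_symmetry_invariance(self):
        sig, mask, field = self._disc_setup()
        ar1, _ = met.aspect_ratio(sig, mask, field)
        ar2, _ = met.aspect_ratio(sig[:, :, ::-1].copy(), mask, field)
        assert ar2 == pytest.approx(ar1, rel=1e-6)

    def test_zero_signal_flagged_undefined(self):
        sig, mask, field = self._disc_setup()
        ar, flags = met.aspect_ratio(np.zeros_like(sig), mask, field)
        assert math.isnan(ar)
        assert "undefined_ar" in flags

    def test_single_column_capped_and_flagged(self):
        region = synthetic_region(nz=2)
        curve = straight_curve(10.0)
        field = met.distance_field(curve, region)
        mask = met.integration_region(region, curve, 0.0, field=field)
        sig = np.zeros((2, 100, 60))
        sig[:, 40:60, 30] = 1.0
        ar, flags = met.aspect_ratio(sig, mask, field, cap=100.0)
        assert ar == 100.0
        assert "ar_capped" in flags

    def test_elongation_increases_aspect_ratio(self):
        geom = aq.make_device_geometry(SMALL_GEOM)
        cps = straight_cps(geom)
        ars = []
        for L in (20.0, 40.0, 80.0):
            spr = default_sprout(geom, length_um=L, n_nuclei=0)
            m = aq.ground_truth_metrics([spr], cps, 10.0)
            ars.append(m.AR_cyto)
        assert ars[0] < ars[1] < ars[2]


class TestComputeAndDifferential:
    def test_noiseless_phantom_within_five_percent_of_truth(
        self, noiseless_phantom
    ):
        stack, truth = noiseless_phantom
        st, _ = pp.preprocess_stack(stack)
        region = region_from_truth(truth, st)
        curve = MonolayerCurve(truth.monolayer_control_points)
        m = met.compute_metrics(st, region, curve, truth.offset_um)
        tm = truth.metrics_true
        for f in ("M_cyto", "J_cyto", "M_hoechst", "J_hoechst"):
            assert getattr(m, f) == pytest.approx(getattr(tm, f), rel=0.05), f

    def test_channels_are_independent(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        region = region_from_truth(truth, stack)
        curve = MonolayerCurve(truth.monolayer_control_points)
        m1 = met.compute_metrics(stack, region, curve, 10.0)
        perturbed = stack.with_channels(
            {
                k: (v * 3.0 if k == "hoechst" else v.copy())
                for k, v in stack.channels.items()
            }
        )
        m2 = met.compute_metrics(perturbed, region, curve, 10.0)
        assert m2.M_cyto == m1.M_cyto and m2.J_cyto == m1.J_cyto
        assert m2.M_hoechst == pytest.approx(3 * m1.M_hoechst, rel=1e-6)

    def test_offset_monotonicity(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        region = region_from_truth(truth, stack)
        curve = MonolayerCurve(truth.monolayer_control_points)
        Ms, Js = [], []
        for off in (0.0, 10.0, 20.0):
            m = met.compute_metrics(stack, region, curve, off)
            Ms.append(m.M_cyto)
            Js.append(m.J_cyto)
        assert Ms[0] >= Ms[1] >= Ms[2]
        assert Js[0] >= Js[1] >= Js[2]

    def test_subthreshold_noise_changes_M_by_under_one_percent(self):
        rng = np.random.default_rng(3)
        region = synthetic_region(nz=4)
        curve = straight_curve(10.0)
        mask = met.integration_region(region, curve, 0.0)
        clean = np.zeros((4, 100, 60))
        clean[:, 30:70, 20:40] = 0.8
        noisy = clean + rng.normal(0.1, 0.02, clean.shape)
        model = pp.estimate_background(noisy)
        eliminated = np.where(noisy > model.threshold, noisy - model.mu, 0.0)
        M0 = met.total_integral(clean, mask)
        M1 = met.total_integral(eliminated, mask)
        assert abs(M1 - M0) / M0 < 0.01

    def test_identical_timepoints_give_zero_differential(self):
        m = met.AngiogenicMetrics(M_cyto=5.0, J_cyto=50.0, AR_cyto=2.0,
                                  M_hoechst=1.0, J_hoechst=10.0, AR_hoechst=3.0,
                                  timepoint_label="0hr")
        d = met.differential_metrics(m, m)
        assert d.M_cyto == 0 and d.J_cyto == 0 and d.AR_cyto == 0
        assert d.timepoint_label == "diff"

    def test_doubling_growth_gives_delta_equal_to_baseline(self):
        import dataclasses

        m0 = met.AngiogenicMetrics(M_cyto=5.0, J_cyto=50.0)
        m48 = dataclasses.replace(m0, M_cyto=10.0, timepoint_label="48hr")
        d = met.differential_metrics(m0, m48)
        assert d.M_cyto == pytest.approx(m0.M_cyto)

    def test_identifier_mismatch_rejected(self):
        m0 = met.AngiogenicMetrics(device_id="D0", region_index=0)
        m1 = met.AngiogenicMetrics(device_id="D1", region_index=0)
        with pytest.raises(ValueError, match="identifier"):
            met.differential_metrics(m0, m1)
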