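"""Shared helpers for the test suite: a desk-scale phantom geometry and a
constructor for ground-truth gel regions."""

import numpy as np

import angioquant as aq
from angioquant.geometry import GelRegion

#: scaled-down single-region device used throughout the tests: one post
#: period, a 160 um gel strip, 5 z-sections at the reference 1.25 um xy pixels
SMALL_GEOM = {
    "n_regions": 1,
    "gel_width_um": 160.0,
    "channel_width_um": 60.0,
    "stack_depth_um": 40.0,
    "n_z_sections": 5,
    "voxel_size_um": (8.0, 1.25, 1.25),
}

#: coarser variant (2 um pixels) for tests that only need structure, not
#: metric accuracy
COARSE_GEOM = dict(SMALL_GEOM, voxel_size_um=(8.0, 2.0, 2.0))


def straight_cps(geom: "aq.DeviceGeometry", r_um: float = 15.0) -> np.ndarray:
    """A straight monolayer at normal offset ``r_um`` in region coordinates."""
    P = geom.period_um
    return np.array([[0.0, r_um], [P / 3, r_um], [2 * P / 3, r_um], [P, r_um]])


def default_sprout(geom: "aq.DeviceGeometry", **kw) -> "aq.SproutSpec":
    base = dict(
        base_point=(geom.period_um / 2, None),
        length_um=80.0,
        radius_um=10.0,
        n_nuclei=5,
        nucleus_semiaxes_um=(4.0, 5.5, 8.0),
    )
    base.update(kw)
    return aq.SproutSpec(**base)


def region_from_truth(truth: "aq.GroundTruth", stack: "aq.ImageStack") -> GelRegion:
    """Build a GelRegion directly from phantom ground truth (oracle geometry)."""
    return GelRegion(
        boundary_lines=list(truth.boundary_lines),
        x_mid_um=truth.x_mid_um,
        post_polygons=[np.asarray(p) for p in truth.post_polygons],
        region_index=0,
        image_shape=stack.shape,
        voxel_size_um=stack.voxel_size_um,
    )
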