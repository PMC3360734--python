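# angioquant

Automated, unbiased quantification of ensemble three-dimensional angiogenic
growth in microfluidic devices.

In the assay this package models, an endothelial monolayer forms along one
face of a collagen gel strip caged between trapezoidal PDMS posts; growth
factor gradients (e.g. VEGF, S1P) applied across the gel drive sprouting
into the matrix. A device carries tens of gel growth regions imaged as
4-channel confocal stacks (cytosolic stain, nuclear stain, reflected and
transmitted light) at 0 h and 48 h, so each device yields an *ensemble* of
growth observations under common conditions. `angioquant` reimplements the
full quantification chain and validates it end to end on synthetic phantom
stacks with analytic ground truth.

## What it computes

For each gel region and fluorescence signal *s*(**x**) (cytosolic or
nuclear), over the invasion region *V* bounded by the gel/PDMS boundaries,
the post walls and the monolayer offset 10 µm into the gel:

- **M** = ∫_V s(**x**) dV — total signal integral; aggregate growth,
- **J** = ∫_V s(**x**) r(**x**) dV — first moment of the signal with
  respect to the normal distance r(**x**) from the monolayer; penetration,
- **AR** = (∫ s·r / M) ÷ (∫ s·|u−ū| / M) — aspect ratio; directionality of
  invasion (normal penetration over lateral spread along the monolayer
  coordinate u).

Differential metrics (48 h − 0 h, growth-positive) remove each region's
baseline activity. Device- and condition-level aggregation, Student/Welch
t-tests against matched basal controls, the mean–SD scaling analysis of
intrinsic variance (SD ∝ mean, the signature of gamma-distributed sums of
exponential cell-level events), and the optimal regions-per-device
allocation minimizing SE² = σ_m²/m + σ_d²/(m·n) under a region budget are
provided in `angioquant.ensemble`. A finite-difference advection–diffusion
solver (`angioquant.transport`) reproduces the device's steady gradient
behavior, plus the design calculators (Péclet number, Young–Laplace
containment pressure, post-angle supplement).

Because no raw images from this assay are publicly deposited, the package
ships a first-class phantom generator (`angioquant.phantom`) that renders
device stacks — bimodal gel/PDMS reflectance with trapezoidal posts, a
monolayer band, capped-cylinder sprouts with ellipsoidal nuclei, optics
blur and Gaussian background noise — together with closed-form/quadrature
ground-truth metrics, against which the entire detection pipeline is
tested.

## Worked example

```python
import numpy as np
import angioquant as aq
from angioquant import ensemble as ens
from angioquant.config import PipelineConfig
from angioquant.pipeline import run_pipeline

# one desk-scale gel region: 160 um gel strip, 5 z-sections, 1.25 um pixels
geom_overrides = {
    "n_regions": 1, "gel_width_um": 160.0, "channel_width_um": 60.0,
    "stack_depth_um": 40.0, "n_z_sections": 5, "voxel_size_um": (8.0, 1.25, 1.25),
}
geom = aq.make_device_geometry(geom_overrides)
P = geom.period_um
monolayer = np.array([[0.0, 15.0], [P/3, 15.0], [2*P/3, 15.0], [P, 15.0]])
sprout = aq.SproutSpec(base_point=(P/2, None), length_um=80.0, radius_um=10.0,
                       n_nuclei=5, nucleus_semiaxes_um=(4.0, 5.5, 8.0))

stack_0hr, _ = aq.render_stack(geom, monolayer, [], aq.NoiseSpec(0.1, 0.05, 1),
                               timepoint_label="0hr", blur_sigma_um=1.5)
stack_48hr, truth = aq.render_stack(geom, monolayer, [sprout],
                                    aq.NoiseSpec(0.1, 0.05, 2),
                                    timepoint_label="48hr", blur_sigma_um=1.5)

config = PipelineConfig(geometry=geom_overrides)
table, report = run_pipeline(config, [(stack_0hr, stack_48hr)],
                             condition="VEGF Grad.")
diff = table[table.timepoint == "diff"].iloc[0]
print(f"delta M_cyto = {diff.M_cyto:.0f} "
      f"(analytic truth {truth.metrics_true.M_cyto:.0f})")

sim = ens.simulate_ensemble(14, 37, (1.0, 10.0), cv=0.4, seed=1)
device_stats, cond = ens.aggregate(sim, "M_cyto")
slope, intercept, r2 = ens.mean_sd_regression(device_stats)
print(f"mean-SD regression: slope = {slope:.3f}, r^2 = {r2:.3f}")

model = ens.AllocationModel(sigma_d=np.sqrt(7.0), sigma_m=1.0,
                            k_total=200, overhead=5.0)
n, m, se = ens.optimal_allocation(model)
print(f"optimal allocation: {n} regions/device x {m} devices (SE {se:.3f})")
```

Output:

```
delta M_cyto = 21668 (analytic truth 21991)
mean-SD regression: slope = 0.374, r^2 = 0.952
optimal allocation: 5 regions/device x 20 devices (SE 0.346)
```

The pipeline recovers the added sprout's total cytosolic integral within
~1.5% of the analytic cylinder value despite noise, blur and fully
automatic geometry detection. The simulated 14-device ensemble under a
constant coefficient of variation of 0.4 shows the strong linear mean–SD
relation (r² ≈ 0.95) characteristic of multiplicative intrinsic noise, and
with an intrinsic/extrinsic variance ratio of 7 and a 5-region-equivalent
per-device overhead, the design optimizer favors ensemble devices with
multiple growth regions over maximal device replication.

A command-line interface mirrors the library
(`angioquant phantom generate`, `preprocess`, `detect`, `fit-monolayer`,
`metrics`, `pipeline`, `ensemble …`, `transport …`).

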