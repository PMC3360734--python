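"""Ensemble statistics of angiogenic response.

Per-region metrics are aggregated to device and condition level (devices are
the independent replication unit), tested against matched basal controls,
and analyzed for mean-variance scaling.  A stochastic generator simulates
the agent-based picture of angiogenesis — each region's response is an
accumulation of independent exponential cell-level events, hence gamma
distributed — in two regimes: constant coefficient of variation
(SD proportional to the mean, the multiplicative-noise regime observed for
the integral and moment metrics) and constant Fano factor (variance
proportional to the mean).  The allocation model answers the design
question of how many growth regions per device minimize the standard error
of a condition mean for a fixed total budget of regions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CONDITION_LABELS = ("Control", "VEGF Grad.", "VEGF + S1P", "VEGF Grad. + S1P")

#: applied test conditions: concentrations (in excess of basal media) at the
#: monolayer-side and opposite media channels; VEGF in ng/mL, S1P in nM
_CONDITION_TABLE: Dict[str, Tuple[Dict[str, float], Dict[str, float]]] = {
    "Control": ({}, {}),
    "VEGF Grad.": ({"VEGF": 20.0}, {"VEGF": 40.0}),
    "VEGF + S1P": ({"VEGF": 20.0}, {"VEGF": 20.0, "S1P": 250.0}),
    "VEGF Grad. + S1P": ({"VEGF": 20.0}, {"VEGF": 40.0, "S1P": 250.0}),
}


@dataclasses.dataclass(frozen=True)
class ConditionSpec:
    """One applied biochemical condition and its derived nominal fields."""

    label: str
    monolayer_channel: Dict[str, float]
    opposite_channel: Dict[str, float]
    nominal_average: Dict[str, float]
    nominal_gradient: Dict[str, float]


def condition_from_table1(label: str) -> ConditionSpec:
    """Look up an applied condition by label.

    The nominal average across the gel is the arithmetic mean of the two
    channel concentrations per species; the nominal gradient is their
    difference (per gel width).
    """
    if label not in _CONDITION_TABLE:
        raise ValueError(
            f"unknown condition {label!r}; valid labels: {list(CONDITION_LABELS)}"
        )
    mono, opp = _CONDITION_TABLE[label]
    species = sorted(set(mono) | set(opp))
    avg = {s: (mono.get(s, 0.0) + opp.get(s, 0.0)) / 2.0 for s in species}
    grad = {s: opp.get(s, 0.0) - mono.get(s, 0.0) for s in species}
    return ConditionSpec(
        label=label,
        monolayer_channel=dict(mono),
        opposite_channel=dict(opp),
        nominal_average=avg,
        nominal_gradient=grad,
    )


@dataclasses.dataclass
class DeviceStats:
    """Per-device summary of one metric."""

    device_id: str
    condition: str
    mean: float
    sd: float
    n_regions: int


@dataclasses.dataclass(frozen=True)
class AllocationModel:
    """Variance components and budget for the region-allocation problem.

    ``sigma_d`` is the within-device (region-to-region) SD, ``sigma_m`` the
    between-device SD of device means.  ``overhead`` is the per-device cost
    in region-equivalents (setup, seeding, imaging overhead); each device
    with n regions consumes n + overhead units of the total budget
    ``k_total``.
    """

    sigma_d: float
    sigma_m: float
    k_total: int
    overhead: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma_d < 0 or self.sigma_m < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.sigma_d == 0 and self.sigma_m == 0:
            raise ValueError("at least one variance component must be > 0")
        if self.k_total < 1:
            raise ValueError("k_total: must be >= 1")
        if self.overhead < 0:
            raise ValueError("overhead: must be >= 0")
        if self.overhead >= self.k_total:
            raise ValueError("overhead consumes the whole budget")

    def se(self, m: int, n: int) -> float:
        """SE of the condition mean with m devices of n regions each."""
        return math.sqrt(self.sigma_m**2 / m + self.sigma_d**2 / (m * n))


def aggregate(
    table: pd.DataFrame, metric: str
) -> Tuple[List[DeviceStats], pd.DataFrame]:
    """Device means/SDs and condition summaries for one metric.

    The condition mean is the mean of its device means and the condition SE
    is the SD of device means over sqrt(n_devices): devices are the
    independent unit of replication.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table columns")
    if table.empty:
        raise ValueError("empty table")
    dev_stats: List[DeviceStats] = []
    for (cond, dev), grp in sorted(
        table.groupby(["condition", "device_id"], sort=True), key=lambda kv: kv[0]
    ):
        v = grp[metric].to_numpy(dtype=float)
        dev_stats.append(
            DeviceStats(
                device_id=str(dev),
                condition=str(cond),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if len(v) >= 2 else float("nan"),
                n_regions=len(v),
            )
        )
    rows = []
    for cond in sorted({d.condition for d in dev_stats}):
        means = np.array([d.mean for d in dev_stats if d.condition == cond])
        se = (
            float(means.std(ddof=1) / math.sqrt(len(means)))
            if len(means) >= 2
            else float("nan")
        )
        rows.append(
            {
                "condition": cond,
                "mean": float(means.mean()),
                "se": se,
                "n_devices": len(means),
            }
        )
    return dev_stats, pd.DataFrame(rows)


def significance_marker(p: float) -> str:
    """Significance markers: * p<0.1, ** p<0.05, *** p<0.005."""
    if p < 0.005:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def test_vs_control(
    condition_values: Sequence[float],
    control_values: Sequence[float],
    welch: bool = True,
) -> Tuple[float, str]:
    """Two-sample t-test of a condition against its matched basal control.

    Welch's unequal-variance form by default (``welch=False`` for the
    classic pooled-variance test).  Degenerate case (zero variance in both
    groups, equal means) gives p = 1 by convention.
    """
    a = np.asarray(condition_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return p, significance_marker(p)


def mean_sd_regression(
    device_stats: Sequence[DeviceStats],
) -> Tuple[float, float, float]:
    """OLS regression of device SD on device mean: (slope, intercept, r^2).

    A strong linear relation (SD proportional to the mean) is the signature
    of multiplicative intrinsic noise in the region-level response.
    """
    pts = [(d.mean, d.sd) for d in device_stats if not math.isnan(d.sd)]
    if len(pts) < 3:
        raise ValueError("need >= 3 devices for the mean-SD regression")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def simulate_ensemble(
    n_devices: int = 14,
    n_regions: int = 37,
    device_mean_range: Tuple[float, float] = (1.0, 10.0),
    cv: float = 0.4,
    regime: str = "constant-cv",
    cell_event_scale: Optional[float] = None,
    seed: Optional[int] = None,
    condition: str = "Control",
    metric: str = "M_cyto",
) -> pd.DataFrame:
    """Simulate an ensemble of devices under the cell-level event model.

    Each region's response is the accumulation of independent exponential
    cell-level contributions, i.e. gamma distributed.  In the
    ``constant-cv`` regime the gamma shape is 1/cv^2 for every device
    (SD proportional to the mean); in ``constant-fano`` the per-event scale
    ``cell_event_scale`` is fixed, so the shape grows with the device mean
    (variance proportional to the mean).  Device means are log-uniform over
    ``device_mean_range``; the same seed reproduces the table exactly.
    """
    if cv <= 0:
        raise ValueError("cv: must be > 0")
    lo, hi = device_mean_range
    if lo <= 0 or hi < lo:
        raise ValueError("device_mean_range: need 0 < lo <= hi")
    if regime not in ("constant-cv", "constant-fano"):
        raise ValueError("regime: 'constant-cv' or 'constant-fano'")
    rng = np.random.default_rng(seed)
    means = np.exp(rng.uniform(math.log(lo), math.log(hi), n_devices))
    rows = []
    for d, mu in enumerate(means):
        if regime == "constant-cv":
            shape = 1.0 / cv**2
            scale = mu * cv**2
        else:
            theta = cell_event_scale if cell_event_scale is not None else lo * cv**2
            if theta <= 0:
                raise ValueError("cell_event_scale: must be > 0")
            shape = mu / theta
            scale = theta
        vals = rng.gamma(shape, scale, n_regions)
        for r, v in enumerate(vals):
            rows.append(
                {
                    "condition": condition,
                    "device_id": f"D{d:02d}",
                    "region_index": r,
                    "timepoint": "diff",
                    metric: float(v),
                }
            )
    return pd.DataFrame(rows)


def _allocation_key(model: AllocationModel, m: int, n: int) -> Tuple[float, int, int]:
    # prefer smaller SE, then more devices, then fewer regions per device
    return (model.se(m, n), -m, n)


def allocation_oracle(model: AllocationModel) -> Tuple[int, int, float]:
    """Exhaustive search over all feasible integer (regions, devices).

    Returns (n_per_device, n_devices, achieved SE); exact arg-min of
    SE^2 = sigma_m^2/m + sigma_d^2/(m n) subject to
    m (n + overhead) <= k_total.  Ties prefer more devices.
    """
    if model.k_total > 10**4:
        raise ValueError("oracle limited to k_total <= 10^4")
    best = None
    m_max = int(model.k_total // (1 + model.overhead))
    for m in range(1, max(m_max, 1) + 1):
        n_max = int(model.k_total / m - model.overhead)
        for n in range(1, max(n_max, 0) + 1):
            key = _allocation_key(model, m, n)
            if best is None or key < best:
                best = key
                arg = (n, m)
    if best is None:
        raise ValueError("no feasible allocation under the budget")
    return arg[0], arg[1], best[0]


def optimal_allocation(model: AllocationModel) -> Tuple[int, int, float]:
    """Minimize the condition-mean SE over integer (regions, devices).

    For fixed m the SE is non-increasing in n, so only the maximal feasible
    n per device count matters (n = 1 when sigma_d = 0, where region count
    is irrelevant); the device count is then searched exhaustively.  Agrees
    exactly with :func:`allocation_oracle`.
    """
    best = None
    m_max = int(model.k_total // (1 + model.overhead))
    if m_max < 1:
        raise ValueError("no feasible allocation under the budget")
    for m in range(1, m_max + 1):
        n_max = int(model.k_total / m - model.overhead)
        if n_max < 1:
            continue
        n = 1 if model.sigma_d == 0 else n_max
        key = _allocation_key(model, m, n)
        if best is None or key < best:
            best = key
            arg = (n, m)
    return arg[0], arg[1], best[0]


def optimal_regions_continuous(model: AllocationModel) -> float:
    """Continuous-relaxation optimum of regions per device.

    Substituting m = k / (n + overhead) into SE^2 gives
    SE^2(n) = [sigma_m^2 + sigma_d^2 / n] (n + overhead) / k, minimized at
    n* = sigma_d / sigma_m * sqrt(overhead): the ratio sigma_d^2 / sigma_m^2
    (relative intrinsic vs extrinsic variance) sets how many regions each
    device should carry.  With zero per-device overhead the relaxation
    degenerates to n* = 0 (pure device replication), which is why the cost
    model carries an overhead term.
    """
    if model.sigma_m == 0:
        return float("inf")
    return model.sigma_d / model.sigma_m * math.sqrt(model.overhead)


def variance_ratio(table: pd.DataFrame, metric: str) -> float:
    """Within-device over between-device variance ratio.

    Pooled region-to-region variance divided by the variance of device
    means; the standard one-way decomposition ratio sigma_d^2 / Var(means).
    Large values favor ensemble devices with many growth regions.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table columns")
    groups = [g[metric].to_numpy(dtype=float) for _, g in table.groupby("device_id")]
    if len(groups) < 2:
        raise ValueError("need >= 2 devices")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 regions per device")
    within = float(np.mean([g.var(ddof=1) for g in groups]))
    means = np.array([g.mean() for g in groups])
    between = float(means.var(ddof=1))
    if between == 0:
        return 0.0 if within == 0 else float("inf")
    return within / between
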