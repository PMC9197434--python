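"""End-to-end synthetic test scenarios.

No patient data ships with this package: scenarios pair a synthetic
arterial tree with a voxelized tumor mask and the scalar parameters of the
reference patient case (1,357 ml liver, 310 ml tumor, k_h = 0.100 min^-1,
k_c = 0.415 min^-1, 0.8 s waveform with 0.041/0.121/0.260 m/s
min/mean/max inlet velocity), so every downstream stage can run without
external inputs. Tumor masks are unions of ellipsoids, emulating a
peripherally vascularized nodule near a subset of outlet tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import brentq

from hepatrunc.hemodynamics import InflowWaveform, PerfusionParams
from hepatrunc.perfusion import VoxelGrid
from hepatrunc.vascular import SyntheticTreeSpec, VesselTree, generate_synthetic_tree


def make_waveform(
    period: float = 0.8,
    v_min: float = 0.041,
    v_mean: float = 0.121,
    v_max: float = 0.260,
    dt_sample: float = 0.01,
    systole_fraction: float = 0.725,
) -> InflowWaveform:
    """Pulsatile inlet velocity waveform hitting the stated min/mean/max.

    Shape: a ``sin^q`` systolic pulse over the first ``systole_fraction``
    of the cycle on a flat diastolic baseline at ``v_min``. The exponent q
    is solved so the trapezoidal mean of the sampled waveform equals
    ``v_mean`` exactly; the peak sample reaches ``v_max`` exactly.
    """
    n = int(round(period / dt_sample))
    if n % 2:
        n += 1
    t = np.linspace(0.0, period, n + 1)
    t_sys = period * systole_fraction
    # align systole end and peak with sample times
    t_sys = round(t_sys / dt_sample / 2) * 2 * dt_sample
    base = np.sin(np.pi * np.clip(t / t_sys, 0.0, 1.0))
    target = (v_mean - v_min) / (v_max - v_min)

    def sampled_mean(q: float) -> float:
        phi = base**q
        return float(np.trapezoid(phi, t) / period) - target

    q = brentq(sampled_mean, 0.5, 8.0, xtol=1e-12)
    v = v_min + (v_max - v_min) * base**q
    return InflowWaveform(period=period, samples=np.column_stack([t, v]))


@dataclass
class ScenarioSpec:
    """Recipe for a consistent tree + tumor-mask pair."""

    tree: SyntheticTreeSpec = dc_field(default_factory=SyntheticTreeSpec)
    liver_volume_ml: float = 1357.0
    tumor_volume_ml: float = 310.0
    tumor_center: tuple[float, float, float] | None = None  # [m]; default: auto
    tumor_axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    extra_lobes: list[tuple[tuple[float, float, float], float]] = dc_field(
        default_factory=list
    )  # (center, radius) additions
    grid_shape: int = 80
    margin: float = 10e-3  # [m] bounding-box padding
    perfusion: PerfusionParams = dc_field(default_factory=PerfusionParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_volume_ml <= 0:
            raise ValueError("tumor volume must be > 0")


def _ellipsoid_mask(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    h = grid.edge_length
    idx = np.indices(grid.shape, dtype=float)
    # voxel centers
    pts = [grid.origin[k] + (idx[k] + 0.5) * h for k in range(3)]
    val = sum(((pts[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3))
    return val <= 1.0


def build_scenario(spec: ScenarioSpec) -> tuple[VesselTree, VoxelGrid, dict]:
    """Generate a tree and an embedded tumor mask on a fitted voxel grid.

    The tumor is an ellipsoid (plus optional extra lobes) whose volume
    matches ``tumor_volume_ml``; by default it is centered beyond the
    distal half of the tree so that a subset of outlets perfuse it. The
    cubic voxel grid spans vessels + tumor + margin.
    """
    tree = generate_synthetic_tree(spec.tree)
    pts = np.vstack([b.centerline for b in tree.branches])

    r_t = (3.0 * spec.tumor_volume_ml * 1e-6 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = np.asarray(spec.tumor_axis_ratios, dtype=float)
    semi = r_t * ratios / np.prod(ratios) ** (1.0 / 3.0)
    if spec.tumor_center is None:
        # beyond the distal tips, shifted off-axis so territories differ
        tips = np.array([b.centerline[-1] for b in tree.leaves])
        center = tips.mean(axis=0) + np.array([0.6, 0.3, 0.0]) * r_t
    else:
        center = np.asarray(spec.tumor_center, dtype=float)

    lo = np.minimum(pts.min(axis=0), center - semi) - spec.margin
    hi = np.maximum(pts.max(axis=0), center + semi) + spec.margin
    edge = float(np.max(hi - lo) / spec.grid_shape)
    shape = (spec.grid_shape,) * 3
    grid = VoxelGrid(
        shape=shape,
        edge_length=edge,
        origin=lo,
        tumor_mask=np.zeros(shape, dtype=bool),
    )
    mask = _ellipsoid_mask(grid, center, semi)
    for lobe_center, lobe_radius in spec.extra_lobes:
        mask |= _ellipsoid_mask(grid, np.asarray(lobe_center), np.full(3, lobe_radius))
    if not mask.any():
        raise ValueError("tumor mask is empty; enlarge the grid or tumor")
    grid.tumor_mask = mask

    config = {
        "liver_volume_ml": spec.liver_volume_ml,
        "tumor_volume_ml": spec.tumor_volume_ml,
        "perfusion": {"k_h": spec.perfusion.k_h, "k_c": spec.perfusion.k_c},
        "inlet_area_m2": float(np.pi * tree.root.radius**2),
        "rng_seed": spec.rng_seed,
    }
    return tree, grid, config


def scenario_preset(name: str, seed: int = 0) -> ScenarioSpec:
    """Named study conditions.

    ``patient_like``: 48 outlets, 310 ml spherical tumor, reference
    constants. ``well_mixed``: a long straight parent feeding a symmetric
    small subtree (tracer exit fractions should match flow fractions).
    ``degenerate``: a small tumor entirely inside one outlet's territory.
    """
    if name == "patient_like":
        return ScenarioSpec(
            tree=SyntheticTreeSpec(n_outlets=48, rng_seed=seed),
            grid_shape=100,
            rng_seed=seed,
        )
    if name == "well_mixed":
        return ScenarioSpec(
            tree=SyntheticTreeSpec(
                n_outlets=6,
                root_length=60e-3,
                branch_length=25e-3,
                rng_seed=seed,
            ),
            tumor_volume_ml=120.0,
            grid_shape=64,
            rng_seed=seed,
        )
    if name == "degenerate":
        # small nodule (radius ~6 mm) so it sits well inside one territory
        return ScenarioSpec(
            tree=SyntheticTreeSpec(n_outlets=4, rng_seed=seed),
            tumor_volume_ml=1.0,
            grid_shape=64,
            rng_seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def degenerate_scenario(seed: int = 0) -> tuple[VesselTree, VoxelGrid, dict]:
    """Small tumor centered on one outlet tip: that outlet gets TPP = 100%."""
    spec = scenario_preset("degenerate", seed)
    tree = generate_synthetic_tree(spec.tree)
    tip = tree.leaves[0].centerline[-1]
    spec.tumor_center = tuple(tip + 1e-3)
    return build_scenario(spec)
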