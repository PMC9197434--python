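"""Outlet flow boundary conditions and inflow waveform scaling.

Healthy outflow of an outlet comes from the volume of the Couinaud segment
it perfuses (``Q_s = V_s * k_h``) split symmetrically over the segment's
intrasegmental junctions (1/2 per bifurcation, 1/3 per trifurcation).
Tumoral outflow comes from the tumor volume and the cancerous perfusion
rate (``Q_t = V_t * k_c``) split by tumor perfusion percentage. The outlet
outflow is their sum, and mass conservation fixes the total inflow, which
scales the pulsatile inlet velocity waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from hepatrunc.perfusion import PerfusionMap
from hepatrunc.truncation import TruncationReport
from hepatrunc.vascular import VesselTree

#: Default Couinaud segmental volume fractions [% of total liver volume].
#: Literature-informed round numbers summing to 100; override per patient.
DEFAULT_SEGMENT_FRACTIONS: dict[str, float] = {
    "I": 2.5,
    "II": 7.5,
    "III": 9.0,
    "IV": 16.0,
    "V": 14.5,
    "VI": 12.0,
    "VII": 17.0,
    "VIII": 21.5,
}


@dataclass
class PerfusionParams:
    """Perfusion rate constants [1/min] for healthy and cancerous tissue."""

    k_h: float = 0.100
    k_c: float = 0.415

    def __post_init__(self) -> None:
        if self.k_h <= 0 or self.k_c <= 0:
            raise ValueError("perfusion parameters must be > 0")


@dataclass
class SegmentMap:
    """Mapping of outlets to liver segments with volumes and branching fractions.

    ``branching_fraction[outlet]`` is the intrasegmental share of the
    segment flow reaching that outlet; within each segment they sum to 1.
    """

    segment_volumes_ml: dict[str, float]
    outlet_segment: dict[int, str]
    branching_fraction: dict[int, float]
    total_liver_volume_ml: float

    def __post_init__(self) -> None:
        for seg, v in self.segment_volumes_ml.items():
            if v <= 0:
                raise ValueError(f"segment {seg} volume must be > 0")
        per_seg: dict[str, float] = {}
        for oid, seg in self.outlet_segment.items():
            per_seg[seg] = per_seg.get(seg, 0.0) + self.branching_fraction[oid]
        for seg, s in per_seg.items():
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"branching fractions of segment {seg} sum to {s}, not 1"
                )


def branching_fractions(
    tree: VesselTree, outlet_segment: Mapping[int, str]
) -> dict[int, float]:
    """Symmetric intrasegmental flow split along the tree's junctions.

    For each segment, the minimal subtree spanning its outlets is traversed
    from its root; at every junction the flow divides equally among the
    child subtrees that contain outlets of that segment.
    """
    leaves = {b.outlet_id: b.branch_id for b in tree.leaves}
    missing = [o for o in leaves if o not in outlet_segment]
    if missing:
        raise ValueError(f"outlets {sorted(missing)} not mapped to a segment")
    bf: dict[int, float] = {}
    segments = set(outlet_segment.values())
    for seg in segments:
        outlets = [o for o, s in outlet_segment.items() if s == seg and o in leaves]
        # count, per branch, how many of this segment's outlets sit below it
        counts: dict[int, int] = {}
        for o in outlets:
            for bid in tree.path_to_root(leaves[o]):
                counts[bid] = counts.get(bid, 0) + 1
        for o in outlets:
            share = 1.0
            path = tree.path_to_root(leaves[o])[::-1]  # root ... leaf
            for bid in path[:-1]:
                kids = tree.children(bid)
                active = [k for k in kids if counts.get(k.branch_id, 0) > 0]
                if len(active) > 1:
                    share /= len(active)
            bf[o] = share
    return bf


def segment_map_from_tree(
    tree: VesselTree,
    outlet_segment: Mapping[int, str],
    total_liver_volume_ml: float = 1357.0,
    segment_fractions: Mapping[str, float] | None = None,
) -> SegmentMap:
    """Build a :class:`SegmentMap` scaling literature segment fractions.

    Only segments actually perfused by an outlet receive volume; the
    fractions of the perfused segments are renormalized so the sum of the
    segment volumes equals the total liver volume.
    """
    fr = dict(segment_fractions or DEFAULT_SEGMENT_FRACTIONS)
    used = sorted(set(outlet_segment.values()))
    for seg in used:
        if seg not in fr:
            raise ValueError(f"no volume fraction for segment {seg!r}")
    norm = sum(fr[s] for s in used)
    volumes = {s: total_liver_volume_ml * fr[s] / norm for s in used}
    return SegmentMap(
        segment_volumes_ml=volumes,
        outlet_segment=dict(outlet_segment),
        branching_fraction=branching_fractions(tree, outlet_segment),
        total_liver_volume_ml=total_liver_volume_ml,
    )


@dataclass
class FlowBC:
    """Per-outlet healthy/tumoral/total outflows [ml/min].

    ``Q_b = Q_h + Q_t`` per outlet; ``total_inflow`` is fixed by mass
    conservation as the sum of the outflows.
    """

    Q_h: dict[int, float]
    Q_t: dict[int, float]
    Q_b: dict[int, float] = field(default_factory=dict)
    Q_t_total: float = 0.0
    total_inflow: float = 0.0

    def __post_init__(self) -> None:
        if set(self.Q_h) != set(self.Q_t):
            raise ValueError("healthy and tumoral outflow outlet sets differ")
        if not self.Q_b:
            self.Q_b = {o: self.Q_h[o] + self.Q_t[o] for o in self.Q_h}
        for o, q in self.Q_b.items():
            if q < 0:
                raise ValueError(f"negative flow at outlet {o}")
        if not self.Q_t_total:
            self.Q_t_total = sum(self.Q_t.values())
        self.total_inflow = sum(self.Q_b.values())

    @property
    def healthy_inflow(self) -> float:
        return sum(self.Q_h.values())

    @property
    def tumoral_inflow(self) -> float:
        return sum(self.Q_t.values())

    def fraction_of_inflow(self) -> dict[int, float]:
        """Per-outlet share of total inflow [%]."""
        return {o: 100.0 * q / self.total_inflow for o, q in self.Q_b.items()}


def healthy_outflows(seg: SegmentMap, params: PerfusionParams) -> dict[int, float]:
    """Per-outlet healthy flow [ml/min]: segment volume times the healthy
    perfusion rate, split by the intrasegmental branching fraction."""
    out = {}
    for oid, segment in seg.outlet_segment.items():
        q_s = seg.segment_volumes_ml[segment] * params.k_h
        out[oid] = q_s * seg.branching_fraction[oid]
    return out


def tumor_outflows(
    tpp: PerfusionMap, params: PerfusionParams
) -> tuple[dict[int, float], float]:
    """Per-outlet tumoral flow [ml/min] and the total tumoral flow.

    ``Q_t = V_t * k_c``; each outlet receives its TPP share of it.
    """
    total = sum(tpp.tpp_by_outlet.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"TPPs must sum to 100%, got {total}")
    q_t = tpp.tumor_volume_ml * params.k_c
    per_outlet = {o: q_t * p / 100.0 for o, p in tpp.tpp_by_outlet.items()}
    return per_outlet, q_t


def assemble_bc(
    healthy: Mapping[int, float], tumoral: Mapping[int, float]
) -> FlowBC:
    """Combine healthy and tumoral outflows into outlet boundary conditions."""
    h = dict(healthy)
    t = dict(tumoral)
    # outlets present on one side only carry zero flow on the other
    for o in set(h) | set(t):
        h.setdefault(o, 0.0)
        t.setdefault(o, 0.0)
    return FlowBC(Q_h=h, Q_t=t)


def merge_flow_bc(bc: FlowBC, report: TruncationReport) -> FlowBC:
    """Fold boundary conditions through a truncation (flows sum over members)."""
    q_h = {}
    q_t = {}
    for rid, members in report.merged_groups:
        q_h[rid] = sum(bc.Q_h[m] for m in members)
        q_t[rid] = sum(bc.Q_t[m] for m in members)
    return FlowBC(Q_h=q_h, Q_t=q_t)


def flow_fractions(
    full_bc: FlowBC, report: TruncationReport
) -> dict[int, dict[int, float]]:
    """Flow fraction FF of each original outlet under its truncated outlet.

    ``FF = Q_member / Q_truncated`` with ``Q_truncated = sum of member Q``;
    an un-truncated outlet maps to itself with FF = 1.
    """
    ff: dict[int, dict[int, float]] = {}
    for rid, members in report.merged_groups:
        q_star = sum(full_bc.Q_b[m] for m in members)
        if q_star <= 0:
            raise ValueError(f"truncated outlet {rid} has zero total flow")
        ff[rid] = {m: full_bc.Q_b[m] / q_star for m in members}
    return ff


@dataclass
class InflowWaveform:
    """Periodic inlet velocity waveform, sampled as (time [s], velocity [m/s])."""

    period: float
    samples: np.ndarray  # (n, 2): time, velocity
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array")
        t = self.samples[:, 0]
        if not (math.isclose(t[0], 0.0, abs_tol=1e-12) and
                math.isclose(t[-1], self.period, rel_tol=1e-9)):
            raise ValueError("samples must span [0, period]")
        v0, v1 = self.samples[0, 1], self.samples[-1, 1]
        if not math.isclose(v0, v1, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("waveform must be periodic (first == last sample)")

    @property
    def velocities(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def v_min(self) -> float:
        return float(self.velocities.min())

    @property
    def v_max(self) -> float:
        return float(self.velocities.max())

    @property
    def v_mean(self) -> float:
        """Time-averaged velocity over one period (trapezoidal)."""
        return float(
            np.trapezoid(self.velocities, self.samples[:, 0]) / self.period
        )

    def velocity_at(self, t: float | np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of the velocity at time(s) ``t``."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        return np.interp(tt, self.samples[:, 0], self.velocities)

    def scaled(self, factor: float) -> "InflowWaveform":
        s = self.samples.copy()
        s[:, 1] *= factor
        return InflowWaveform(
            period=self.period, samples=s, scale_factor=self.scale_factor * factor
        )


def scale_waveform(
    w: InflowWaveform, bc: FlowBC, inlet_area: float
) -> InflowWaveform:
    """Scale velocities so the mean volumetric inflow matches the BC total.

    ``inlet_area`` is in m²; ``bc.total_inflow`` in ml/min is converted to
    m³/s. The scaled waveform's time-averaged flow matches within 0.1%.
    """
    if inlet_area <= 0:
        raise ValueError("inlet area must be > 0")
    if w.v_mean <= 0:
        raise ValueError("waveform mean velocity must be > 0")
    target_m3s = bc.total_inflow * 1e-6 / 60.0
    factor = target_m3s / (w.v_mean * inlet_area)
    out = w.scaled(factor)
    achieved = out.v_mean * inlet_area
    if abs(achieved - target_m3s) > 1e-3 * target_m3s:
        raise RuntimeError("waveform scaling failed to match target inflow")
    return out
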