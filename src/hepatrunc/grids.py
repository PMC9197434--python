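"""Particle Grid methodology: PRM -> PRG -> CPRG, and distribution estimators.

A Particle Release Map (PRM) records, for one injection burst, the fate of
each injection position on the axial plane. Rasterizing a PRM on a uniform
reference grid (default spacing 1e-4 m) gives a Particle Release Grid
(PRG) whose cells are classified as tumor / healthy / no-exit /
spatially-uncertain / no-value. Combining the PRGs of several injection
timings yields the Composite PRG (CPRG) with strict >75% / >50% / >37.5%
majority rules.

Cell fractions (CF) and exit fractions (EF) quantify per-outlet particle
distribution; their truncated variants (TCF/TEF) extend a distribution on
a pruned tree back to the full outlet set via flow fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hepatrunc.transport import ExitRecordSet
from hepatrunc.vascular import HEALTHY, TUMOR

# PRG cell states
TUMOR_CELL = "tumor"
HEALTHY_CELL = "healthy"
NO_EXIT_CELL = "no_exit"
SPATIALLY_UNCERTAIN = "spatially_uncertain"
NO_VALUE = "no_value"

# CPRG cell states
TUMOR_CONSTANT = "tumor_constant"
HEALTHY_CONSTANT = "healthy_constant"
NO_EXIT_CONSTANT = "no_exit_constant"
TUMOR_MOSTLY = "tumor_mostly"
HEALTHY_MOSTLY = "healthy_mostly"
TEMPORALLY_UNCERTAIN = "temporally_uncertain"

NO_EXIT_FATE = -1  # fate code in PRMs for particles that never exited


@dataclass
class PRM:
    """Particle release map for one injection timing."""

    timing: float  # [s]
    positions: np.ndarray  # (n, 2) in-plane [m]
    fates: np.ndarray  # (n,) outlet id or NO_EXIT_FATE

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.fates = np.asarray(self.fates, dtype=int)
        if self.positions.shape[0] != self.fates.shape[0]:
            raise ValueError("positions and fates must have equal length")


def prms_from_exits(exits: ExitRecordSet) -> list[PRM]:
    """Split an exit record set into one PRM per injection timing."""
    out = []
    for t in np.unique(exits.injection_time):
        sel = exits.injection_time == t
        out.append(
            PRM(
                timing=float(t),
                positions=exits.injection_xy[sel],
                fates=exits.exit_outlet[sel],
            )
        )
    return out


@dataclass
class PRG:
    """Rasterized PRM: classified cells plus per-cell outlet tallies."""

    timing: float
    spacing: float
    origin: np.ndarray  # (2,) grid anchor [m]
    shape: tuple[int, int]
    states: np.ndarray  # (ni, nj) of state strings (object dtype)
    tallies: dict[tuple[int, int], dict[int, int]] = field(default_factory=dict)

    def cell_of(self, xy: np.ndarray) -> np.ndarray:
        return np.floor((np.atleast_2d(xy) - self.origin) / self.spacing).astype(int)


def rasterize_prg(
    prm: PRM,
    tissue_map: Mapping[int, str],
    spacing: float = 1e-4,
    origin: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
) -> PRG:
    """Classify grid cells from the particle fates inside each cell.

    All particles tumor -> ``tumor``; all healthy -> ``healthy``; all stuck
    -> ``no_exit``; any mixture -> ``spatially_uncertain``; no particles ->
    ``no_value``. ``tissue_map`` maps outlet id to ``tumor``/``healthy``.
    """
    for oid in np.unique(prm.fates):
        if oid != NO_EXIT_FATE and int(oid) not in tissue_map:
            raise ValueError(f"fate references outlet {oid} missing from tissue map")
    if origin is None or shape is None:
        lo = prm.positions.min(axis=0)
        hi = prm.positions.max(axis=0)
        origin = np.floor(lo / spacing) * spacing
        shape = tuple((np.floor(hi / spacing) - np.floor(lo / spacing)).astype(int) + 1)
    origin = np.asarray(origin, dtype=float)

    states = np.full(shape, NO_VALUE, dtype=object)
    tallies: dict[tuple[int, int], dict[int, int]] = {}
    idx = np.floor((prm.positions - origin) / spacing).astype(int)
    for (i, j), fate in zip(map(tuple, idx), prm.fates):
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise ValueError("particle position outside the reference grid")
        tallies.setdefault((i, j), {}).setdefault(int(fate), 0)
        tallies[(i, j)][int(fate)] += 1

    for (i, j), counts in tallies.items():
        kinds = set()
        for fate in counts:
            if fate == NO_EXIT_FATE:
                kinds.add(NO_EXIT_CELL)
            elif tissue_map[fate] == TUMOR:
                kinds.add(TUMOR_CELL)
            elif tissue_map[fate] == HEALTHY:
                kinds.add(HEALTHY_CELL)
            else:
                raise ValueError(f"outlet {fate} has tissue label {tissue_map[fate]!r}")
        if kinds == {TUMOR_CELL}:
            states[i, j] = TUMOR_CELL
        elif kinds == {HEALTHY_CELL}:
            states[i, j] = HEALTHY_CELL
        elif kinds == {NO_EXIT_CELL}:
            states[i, j] = NO_EXIT_CELL
        else:
            states[i, j] = SPATIALLY_UNCERTAIN
    return PRG(
        timing=prm.timing,
        spacing=spacing,
        origin=origin,
        shape=tuple(shape),
        states=states,
        tallies=tallies,
    )


@dataclass
class CPRG:
    """Composite PRG over several injection timings on one shared grid."""

    spacing: float
    origin: np.ndarray
    shape: tuple[int, int]
    states: np.ndarray
    timings: list[float]


def classify_cprg_cell(states: Sequence[str]) -> str:
    """CPRG rule chain for one cell given its per-timing PRG states.

    Thresholds are strict: >75% for the constant states, >50% for the
    mostly states, >37.5% for no-value / spatially-uncertain (in that
    order), else temporally uncertain.
    """
    n = len(states)
    frac = {s: sum(1 for x in states if x == s) / n for s in set(states)}
    get = frac.get
    if get(TUMOR_CELL, 0.0) > 0.75:
        return TUMOR_CONSTANT
    if get(HEALTHY_CELL, 0.0) > 0.75:
        return HEALTHY_CONSTANT
    if get(NO_EXIT_CELL, 0.0) > 0.75:
        return NO_EXIT_CONSTANT
    if get(TUMOR_CELL, 0.0) > 0.5:
        return TUMOR_MOSTLY
    if get(HEALTHY_CELL, 0.0) > 0.5:
        return HEALTHY_MOSTLY
    if get(NO_VALUE, 0.0) > 0.375:
        return NO_VALUE
    if get(SPATIALLY_UNCERTAIN, 0.0) > 0.375:
        return SPATIALLY_UNCERTAIN
    return TEMPORALLY_UNCERTAIN


def compose_cprg(prgs: Sequence[PRG]) -> CPRG:
    """Combine PRGs of several timings cell-by-cell into a CPRG."""
    if len(prgs) < 2:
        raise ValueError("a CPRG needs at least 2 PRGs")
    first = prgs[0]
    for p in prgs[1:]:
        if (
            p.shape != first.shape
            or not math.isclose(p.spacing, first.spacing)
            or not np.allclose(p.origin, first.origin)
        ):
            raise ValueError("all PRGs must share an identical reference grid")
    states = np.empty(first.shape, dtype=object)
    for i in range(first.shape[0]):
        for j in range(first.shape[1]):
            states[i, j] = classify_cprg_cell([p.states[i, j] for p in prgs])
    return CPRG(
        spacing=first.spacing,
        origin=first.origin.copy(),
        shape=first.shape,
        states=states,
        timings=[p.timing for p in prgs],
    )


@dataclass
class DistributionResult:
    """Per-outlet particle distribution fractions plus the no-exit share."""

    fractions: dict[int, float]
    no_exit_fraction: float = 0.0
    geometry_label: str = ""
    kind: str = "CF"  # CF, TCF, EF or TEF

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outlet_id": sorted(self.fractions),
                "fraction": [self.fractions[o] for o in sorted(self.fractions)],
            }
        )


def compute_cf(
    prgs: Sequence[PRG],
    geometry_label: str = "",
    cell_window: tuple[slice, slice] | None = None,
) -> DistributionResult:
    """Cell fraction per outlet over cell-timing pairs.

    A cell-timing pair counts for outlet x iff all particles in that cell
    at that timing exited through x; pure no-exit cells count toward the
    no-exit term. Spatially uncertain and empty cell-timings enter neither
    numerator nor denominator. ``cell_window`` restricts the count to a
    sub-grid (the catheter-associated section used for tumor dose).
    """
    per_outlet: dict[int, int] = {}
    n_no_exit = 0
    for prg in prgs:
        for (i, j), counts in prg.tallies.items():
            if cell_window is not None:
                si, sj = cell_window
                if not (
                    (si.start or 0) <= i < (si.stop if si.stop is not None else prg.shape[0])
                    and (sj.start or 0) <= j < (sj.stop if sj.stop is not None else prg.shape[1])
                ):
                    continue
            state = prg.states[i, j]
            if state == NO_EXIT_CELL:
                n_no_exit += 1
            elif state in (TUMOR_CELL, HEALTHY_CELL):
                (outlet,) = counts.keys() if len(counts) == 1 else (None,)
                if outlet is None:
                    # several outlets of the same tissue type in one cell:
                    # not attributable to a single outlet -> excluded
                    continue
                per_outlet[outlet] = per_outlet.get(outlet, 0) + 1
    denom = sum(per_outlet.values()) + n_no_exit
    if denom == 0:
        raise ValueError("no classifiable cell-timing pairs; CF undefined")
    return DistributionResult(
        fractions={o: c / denom for o, c in per_outlet.items()},
        no_exit_fraction=n_no_exit / denom,
        geometry_label=geometry_label,
        kind="CF",
    )


def compute_ef(exits: ExitRecordSet, geometry_label: str = "") -> DistributionResult:
    """Exit fraction per outlet over exited particles (catheter injections);
    the no-exit fraction is reported relative to all injected particles."""
    exited = exits.exit_outlet[exits.exit_outlet >= 0]
    if exited.size == 0:
        raise ValueError("no particle exited; EF undefined")
    uniq, counts = np.unique(exited, return_counts=True)
    return DistributionResult(
        fractions={int(o): c / exited.size for o, c in zip(uniq, counts)},
        no_exit_fraction=exits.n_no_exit / exits.n_injected,
        geometry_label=geometry_label,
        kind="EF",
    )


def hybrid_redistribute(
    dist: DistributionResult, ff: Mapping[int, Mapping[int, float]]
) -> DistributionResult:
    """Extend a distribution on a truncated tree to the full outlet set.

    Each truncated outlet's value is split over its member outlets by flow
    fraction (TCF = CF* x FF); outlets absent from ``ff`` pass through.
    """
    out: dict[int, float] = {}
    for oid, value in dist.fractions.items():
        if oid in ff:
            members = ff[oid]
            total_ff = sum(members.values())
            if abs(total_ff - 1.0) > 1e-9:
                raise ValueError(
                    f"flow fractions of truncated outlet {oid} sum to {total_ff}"
                )
            for m, f in members.items():
                out[m] = out.get(m, 0.0) + value * f
        else:
            out[oid] = out.get(oid, 0.0) + value
    return DistributionResult(
        fractions=out,
        no_exit_fraction=dist.no_exit_fraction,
        geometry_label=dist.geometry_label,
        kind="T" + dist.kind if not dist.kind.startswith("T") else dist.kind,
    )


@dataclass
class ComparisonSummary:
    """Per-outlet absolute differences between two distributions [pp]."""

    median: float
    iqr: float
    min: float
    max: float
    argmax_outlet: int
    differences: dict[int, float]


def compare_distributions(
    a: DistributionResult, b: DistributionResult
) -> ComparisonSummary:
    """Outlet-wise |a - b| in percentage points with summary statistics."""
    keys = set(a.fractions) | set(b.fractions)
    if not (set(a.fractions) <= keys and set(b.fractions) <= keys):
        raise ValueError("outlet index mismatch")
    diffs = {
        o: 100.0 * abs(a.fractions.get(o, 0.0) - b.fractions.get(o, 0.0))
        for o in sorted(keys)
    }
    vals = np.array(list(diffs.values()))
    q1, q3 = np.percentile(vals, [25, 75])
    argmax = max(diffs, key=diffs.get)
    return ComparisonSummary(
        median=float(np.median(vals)),
        iqr=float(q3 - q1),
        min=float(vals.min()),
        max=float(vals.max()),
        argmax_outlet=int(argmax),
        differences=diffs,
    )
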