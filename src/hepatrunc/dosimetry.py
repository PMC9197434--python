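"""Monte Carlo tumor-dose distribution over sampled catheter tip locations.

The tumor dose (TD) of a catheter-associated grid section is the sum over
outlets of the section's cell fraction times the tumoral share of that
outlet's flow, ``TD = sum_x CF_x * Q_t,x / (Q_t,x + Q_h,x)``, in percent.
Shifting the section uniformly over the admissible cells of the injection
plane yields a distribution of TDs quantifying sensitivity to catheter tip
placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hepatrunc.grids import NO_VALUE, PRG, DistributionResult, compute_cf
from hepatrunc.hemodynamics import FlowBC


@dataclass
class SamplingSet:
    n_samples: int = 50
    section_half_width: int = 3  # cells; 3 -> 7x7 section
    rng_seed: int = 0
    with_replacement: bool = False


@dataclass
class TumorDoseResult:
    td_samples: np.ndarray  # [%]
    cells: np.ndarray  # (n, 2) sampled center-cell indices
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.td_samples = np.asarray(self.td_samples, dtype=float)
        if np.any((self.td_samples < 0) | (self.td_samples > 100)):
            raise ValueError("TD samples must lie in [0, 100]%")

    @property
    def td_min(self) -> float:
        return float(self.td_samples.min())

    @property
    def td_median(self) -> float:
        return float(np.median(self.td_samples))

    @property
    def td_max(self) -> float:
        return float(self.td_samples.max())

    @property
    def spread(self) -> float:
        return self.td_max - self.td_min


def admissible_cells(grid, half_width: int = 3) -> np.ndarray:
    """Cells around which a full (2w+1)^2 valued square fits.

    A cell is admissible iff no cell of the square window centered on it is
    ``no_value`` (and the window lies inside the grid). ``grid`` may be a
    PRG or CPRG. Returns an (n, 2) index array.
    """
    states = grid.states
    ni, nj = states.shape
    valued = states != NO_VALUE
    w = half_width
    out = []
    for i in range(w, ni - w):
        for j in range(w, nj - w):
            if np.all(valued[i - w : i + w + 1, j - w : j + w + 1]):
                out.append((i, j))
    if not out:
        raise ValueError("no admissible cells; grid too small or too sparse")
    return np.array(out, dtype=int)


def tumor_dose(section_cf: DistributionResult, bc: FlowBC) -> float:
    """TD [%] of a grid-section cell fraction under the flow boundary
    conditions (tumoral flow share per outlet)."""
    td = 0.0
    for oid, cf in section_cf.fractions.items():
        q_t = bc.Q_t.get(oid)
        q_h = bc.Q_h.get(oid)
        if q_t is None or q_h is None:
            raise ValueError(f"no flows for outlet {oid}")
        if q_t + q_h <= 0:
            raise ValueError(f"outlet {oid} has zero total flow")
        td += cf * q_t / (q_t + q_h)
    return 100.0 * td


def section_cf(
    prgs: list[PRG], center: tuple[int, int], half_width: int
) -> DistributionResult:
    """Cell fraction restricted to the square section around ``center``."""
    i, j = center
    w = half_width
    window = (slice(i - w, i + w + 1), slice(j - w, j + w + 1))
    return compute_cf(prgs, cell_window=window)


def td_distribution(
    prgs: list[PRG],
    bc: FlowBC,
    sampling: SamplingSet | None = None,
    admissibility_grid=None,
    ff=None,
) -> TumorDoseResult:
    """TDs at randomly sampled catheter tip cells (uniform over admissible).

    ``admissibility_grid`` defaults to the first PRG; pass a CPRG to use
    its no-value pattern instead. When ``ff`` (flow-fraction map of a
    truncated tree) is given, each section CF is redistributed to the full
    outlet set before the dose sum.
    """
    sampling = sampling or SamplingSet()
    grid = admissibility_grid if admissibility_grid is not None else prgs[0]
    cells = admissible_cells(grid, sampling.section_half_width)
    rng = np.random.default_rng(sampling.rng_seed)
    if sampling.with_replacement:
        pick = rng.integers(0, cells.shape[0], size=sampling.n_samples)
    else:
        if sampling.n_samples > cells.shape[0]:
            raise ValueError(
                f"cannot draw {sampling.n_samples} distinct cells from "
                f"{cells.shape[0]} admissible ones"
            )
        pick = rng.choice(cells.shape[0], size=sampling.n_samples, replace=False)
    tds = []
    for k in pick:
        cf = section_cf(prgs, tuple(cells[k]), sampling.section_half_width)
        if ff is not None:
            from hepatrunc.grids import hybrid_redistribute

            cf = hybrid_redistribute(cf, ff)
        tds.append(tumor_dose(cf, bc))
    return TumorDoseResult(
        td_samples=np.array(tds), cells=cells[pick], rng_seed=sampling.rng_seed
    )
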