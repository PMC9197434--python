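import itertools

import numpy as np
import pytest

from hepatrunc.grids import (
    CPRG,
    HEALTHY_CELL,
    HEALTHY_CONSTANT,
    HEALTHY_MOSTLY,
    NO_EXIT_CELL,
    NO_EXIT_CONSTANT,
    NO_EXIT_FATE,
    NO_VALUE,
    PRM,
    SPATIALLY_UNCERTAIN,
    TEMPORALLY_UNCERTAIN,
    TUMOR_CELL,
    TUMOR_CONSTANT,
    TUMOR_MOSTLY,
    DistributionResult,
    classify_cprg_cell,
    compare_distributions,
    compose_cprg,
    compute_cf,
    compute_ef,
    hybrid_redistribute,
    rasterize_prg,
)
from hepatrunc.transport import ExitRecordSet

TISSUE = {1: "tumor", 2: "tumor", 3: "healthy", 4: "healthy"}
H = 1e-4


def prm_of(points_fates, timing=1.6):
    pos = np.array([p for p, _ in points_fates], dtype=float)
    fates = np.array([f for _, f in points_fates], dtype=int)
    return PRM(timing=timing, positions=pos, fates=fates)


def cell_xy(i, j, k=0):
    """k-th of four distinct positions inside cell (i, j)."""
    offs = [(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)]
    return ((i + offs[k][0]) * H, (j + offs[k][1]) * H)


class TestRasterizePrg:
    def test_all_tumor_particles_make_tumor_cell(self):
        prm = prm_of([(cell_xy(0, 0, k), 1) for k in range(4)])
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(2, 2))
        assert prg.states[0, 0] == TUMOR_CELL

    def test_mixed_fates_make_spatially_uncertain(self):
        prm = prm_of([(cell_xy(0, 0, 0), 1), (cell_xy(0, 0, 1), 3)])
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(1, 1))
        assert prg.states[0, 0] == SPATIALLY_UNCERTAIN

    def test_tumor_plus_stuck_is_uncertain_and_pure_stuck_is_no_exit(self):
        prm = prm_of([(cell_xy(0, 0, 0), 1), (cell_xy(0, 0, 1), NO_EXIT_FATE),
                      (cell_xy(1, 0, 0), NO_EXIT_FATE)])
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(2, 1))
        assert prg.states[0, 0] == SPATIALLY_UNCERTAIN
        assert prg.states[1, 0] == NO_EXIT_CELL

    def test_empty_cell_is_no_value(self):
        prm = prm_of([(cell_xy(0, 0), 1)])
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(2, 2))
        assert prg.states[1, 1] == NO_VALUE

    def test_unknown_outlet_rejected(self):
        prm = prm_of([(cell_xy(0, 0), 99)])
        with pytest.raises(ValueError, match="99"):
            rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(1, 1))


class TestComposeCprg:
    def test_seven_of_eight_tumor_is_constant(self):
        states = [TUMOR_CELL] * 7 + [HEALTHY_CELL]
        assert classify_cprg_cell(states) == TUMOR_CONSTANT

    def test_five_of_eight_tumor_is_mostly(self):
        states = [TUMOR_CELL] * 5 + [HEALTHY_CELL] * 3
        assert classify_cprg_cell(states) == TUMOR_MOSTLY

    def test_no_value_strict_threshold_at_three_eighths(self):
        # exactly 37.5% no-value does NOT trigger; 4/8 does
        mixed = [TUMOR_CELL, HEALTHY_CELL, NO_EXIT_CELL]
        assert (
            classify_cprg_cell([NO_VALUE] * 3 + mixed + [HEALTHY_CELL, NO_EXIT_CELL][:2])
            == TEMPORALLY_UNCERTAIN
        )
        assert classify_cprg_cell([NO_VALUE] * 4 + mixed + [TUMOR_CELL]) == NO_VALUE

    def test_exhaustive_eight_timing_rule_audit(self):
        """Enumerate all 8-timing state multisets and re-derive the rule
        chain independently from the counted fractions."""
        kinds = [TUMOR_CELL, HEALTHY_CELL, NO_EXIT_CELL, SPATIALLY_UNCERTAIN, NO_VALUE]
        n = 8
        for combo in itertools.combinations_with_replacement(kinds, n):
            got = classify_cprg_cell(list(combo))
            c = {k: combo.count(k) / n for k in kinds}
            if c[TUMOR_CELL] > 0.75:
                want = TUMOR_CONSTANT
            elif c[HEALTHY_CELL] > 0.75:
                want = HEALTHY_CONSTANT
            elif c[NO_EXIT_CELL] > 0.75:
                want = NO_EXIT_CONSTANT
            elif c[TUMOR_CELL] > 0.5:
                want = TUMOR_MOSTLY
            elif c[HEALTHY_CELL] > 0.5:
                want = HEALTHY_MOSTLY
            elif c[NO_VALUE] > 0.375:
                want = NO_VALUE
            elif c[SPATIALLY_UNCERTAIN] > 0.375:
                want = SPATIALLY_UNCERTAIN
            else:
                want = TEMPORALLY_UNCERTAIN
            assert got == want, combo

    def test_permutation_invariance_of_timing_order(self):
        states = [TUMOR_CELL, HEALTHY_CELL, NO_VALUE, TUMOR_CELL,
                  NO_EXIT_CELL, TUMOR_CELL, SPATIALLY_UNCERTAIN, TUMOR_CELL]
        base = classify_cprg_cell(states)
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = list(rng.permutation(states))
            assert classify_cprg_cell(perm) == base

    def test_compose_requires_identical_grids(self):
        prm = prm_of([(cell_xy(0, 0), 1)])
        a = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(2, 2))
        b = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(3, 3))
        with pytest.raises(ValueError, match="identical"):
            compose_cprg([a, b])

    def test_compose_end_to_end(self):
        prgs = []
        for t in range(8):
            fate = 1 if t < 7 else 3
            prm = prm_of([(cell_xy(0, 0), fate)], timing=1.6 + 0.1 * t)
            prgs.append(rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(1, 1)))
        cprg = compose_cprg(prgs)
        assert cprg.states[0, 0] == TUMOR_CONSTANT
        assert len(cprg.timings) == 8


class TestComputeCf:
    def test_all_cells_one_outlet(self):
        prm = prm_of([(cell_xy(i, j), 1) for i in range(3) for j in range(3)])
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(3, 3))
        cf = compute_cf([prg])
        assert cf.fractions[1] == pytest.approx(1.0)
        assert cf.no_exit_fraction == 0.0

    def test_hand_count_with_uncertain_and_empty_cells(self):
        # 6 cells outlet 1, 2 no-exit, 1 uncertain, 1 empty -> CF = 6/8
        pts = [(cell_xy(i, 0), 1) for i in range(6)]
        pts += [(cell_xy(6, 0), NO_EXIT_FATE), (cell_xy(7, 0), NO_EXIT_FATE)]
        pts += [(cell_xy(8, 0, 0), 1), (cell_xy(8, 0, 1), 3)]  # uncertain
        prm = prm_of(pts)
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(10, 1))
        cf = compute_cf([prg])
        assert cf.fractions[1] == pytest.approx(6 / 8)
        assert cf.no_exit_fraction == pytest.approx(2 / 8)

    def test_aggregates_over_timings(self):
        prgs = []
        for t, fate in [(1.6, 1), (1.7, 3)]:
            prm = prm_of([(cell_xy(0, 0), fate)], timing=t)
            prgs.append(rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(1, 1)))
        cf = compute_cf(prgs)
        assert cf.fractions[1] == pytest.approx(0.5)
        assert cf.fractions[3] == pytest.approx(0.5)

    def test_zero_denominator_rejected(self):
        prm = prm_of([(cell_xy(0, 0, 0), 1), (cell_xy(0, 0, 1), 3)])
        prg = rasterize_prg(prm, TISSUE, H, origin=np.zeros(2), shape=(1, 1))
        with pytest.raises(ValueError, match="CF undefined"):
            compute_cf([prg])


class TestHybridRedistribute:
    def test_equal_trifurcation_worked_example(self):
        dist = DistributionResult(fractions={1: 0.3, 5: 0.7})
        ff = {1: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3}}
        out = hybrid_redistribute(dist, ff)
        assert out.fractions[1] == pytest.approx(0.1)
        assert out.fractions[2] == pytest.approx(0.1)
        assert out.fractions[3] == pytest.approx(0.1)
        assert out.fractions[5] == pytest.approx(0.7)
        assert out.kind == "TCF"

    def test_identity_truncation_passthrough(self):
        dist = DistributionResult(fractions={1: 0.4, 2: 0.6})
        out = hybrid_redistribute(dist, {})
        assert out.fractions == dist.fractions

    def test_member_sums_equal_parent_over_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_trunc = rng.integers(1, 5)
            dist = {}
            ff = {}
            for i in range(n_trunc):
                dist[i] = float(rng.random())
                k = int(rng.integers(2, 5))
                w = rng.random(k)
                ff[i] = {100 * i + j: w[j] / w.sum() for j in range(k)}
            out = hybrid_redistribute(DistributionResult(fractions=dist), ff)
            for i in range(n_trunc):
                total = sum(out.fractions[m] for m in ff[i])
                assert total == pytest.approx(dist[i], rel=1e-12)

    def test_bad_ff_normalization_rejected(self):
        dist = DistributionResult(fractions={1: 0.5})
        with pytest.raises(ValueError, match="sum"):
            hybrid_redistribute(dist, {1: {1: 0.6, 2: 0.6}})


class TestComputeEf:
    def make_exits(self, outlets):
        n = len(outlets)
        return ExitRecordSet(
            injection_xy=np.zeros((n, 2)),
            injection_time=np.zeros(n),
            exit_outlet=np.array(outlets),
            exit_time=np.where(np.array(outlets) >= 0, 1.0, np.nan),
        )

    def test_single_outlet(self):
        ef = compute_ef(self.make_exits([1, 1, 1]))
        assert ef.fractions[1] == pytest.approx(1.0)

    def test_sixty_forty_split_and_no_exit_accounting(self):
        ef = compute_ef(self.make_exits([1] * 6 + [2] * 4 + [-1] * 10))
        assert ef.fractions[1] == pytest.approx(0.6)
        assert ef.fractions[2] == pytest.approx(0.4)
        assert ef.no_exit_fraction == pytest.approx(0.5)

    def test_no_exits_rejected(self):
        with pytest.raises(ValueError, match="EF undefined"):
            compute_ef(self.make_exits([-1, -1]))


class TestCompareDistributions:
    def test_identical_inputs_all_zero(self):
        d = DistributionResult(fractions={1: 0.5, 2: 0.5})
        s = compare_distributions(d, d)
        assert s.median == s.max == 0.0

    def test_single_outlet_difference(self):
        a = DistributionResult(fractions={1: 0.5, 2: 0.5})
        b = DistributionResult(fractions={1: 0.45, 2: 0.55})
        s = compare_distributions(a, b)
        assert s.max == pytest.approx(5.0)  # percentage points
        assert s.median == pytest.approx(5.0)

    def test_matches_brute_force_percentiles(self):
        rng = np.random.default_rng(17)
        fa = rng.random(20)
        fb = rng.random(20)
        a = DistributionResult(fractions=dict(enumerate(fa / fa.sum())))
        b = DistributionResult(fractions=dict(enumerate(fb / fb.sum())))
        s = compare_distributions(a, b)
        diffs = 100 * np.abs(fa / fa.sum() - fb / fb.sum())
        assert s.median == pytest.approx(np.median(diffs))
        assert s.max == pytest.approx(diffs.max())
        q1, q3 = np.percentile(diffs, [25, 75])
        assert s.iqr == pytest.approx(q3 - q1)
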