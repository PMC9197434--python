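"""Tumor-informed two-step pruning of hepatic arterial trees.

Step 1 (:func:`prune_low_tpp`) repeatedly collapses terminal junctions that
contain at least one outlet with TPP at or below the threshold (default 1%).
The feeding branch becomes the new outlet; it is labeled ``tumor`` when the
merged group's total TPP exceeds the threshold, ``healthy`` otherwise.

Step 2 (:func:`merge_same_tissue`) collapses terminal junctions whose leaves
all perfuse the same tissue type; mixed junctions are preserved. Residual
low-TPP leaves that could not be pruned are labeled by the tumor-flow
majority rule (tumor iff the tumoral share of the branch flow exceeds 50%).

Both steps respect two guards: the most proximal junction levels are
protected (default: the first two), and a junction whose feeding branch is
shorter than ``min_cut_space`` offers no room for a cut and is preserved.
Merged outlets take the lowest member outlet id; leaves left shorter than
``short_outlet_limit`` are extruded to ``extension_target``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from hepatrunc.vascular import (
    HEALTHY,
    TUMOR,
    UNASSIGNED,
    VesselTree,
    centerline_length,
    extend_outlet,
)
from hepatrunc.perfusion import PerfusionMap


@dataclass
class TruncationConfig:
    tpp_threshold: float = 1.0  # [%]
    min_cut_space: float = 2.0e-3  # [m]
    short_outlet_limit: float = 5.0e-3  # [m]
    extension_target: float = 20.0e-3  # [m]
    protected_levels: int = 2
    tumor_flow_majority: float = 50.0  # [% of branch flow]

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpp_threshold <= 100.0):
            raise ValueError("tpp_threshold must be in [0, 100]")
        for name in ("min_cut_space", "short_outlet_limit", "extension_target"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class TruncationReport:
    """What a truncation step did: merged groups, extensions, labels."""

    merged_groups: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    extended_outlets: list[int] = field(default_factory=list)
    labels_assigned: dict[int, str] = field(default_factory=dict)
    outlets_before: int = 0
    outlets_after: int = 0

    @property
    def members_by_outlet(self) -> dict[int, tuple[int, ...]]:
        """Resulting outlet id -> original member outlet ids (incl. identity)."""
        return {rid: members for rid, members in self.merged_groups}


def _seed_labels(tree: VesselTree, threshold: float) -> None:
    """Initial tissue labels from TPP: >threshold tumor, zero healthy,
    (0, threshold] left unassigned until a rule resolves them."""
    for leaf in tree.leaves:
        if leaf.tissue_label != UNASSIGNED:
            continue
        if leaf.tpp > threshold:
            leaf.tissue_label = TUMOR
        elif leaf.tpp == 0.0:
            leaf.tissue_label = HEALTHY


def _terminal_junctions(tree: VesselTree) -> list[int]:
    """Branch ids whose children are all leaves, deepest first."""
    out = []
    for b in tree.branches:
        kids = tree.children(b.branch_id)
        if kids and all(not tree.children(k.branch_id) for k in kids):
            out.append(b.branch_id)
    out.sort(key=lambda bid: -len(tree.path_to_root(bid)))
    return out


def _collapsible(tree: VesselTree, bid: int, cfg: TruncationConfig) -> bool:
    if tree.junction_level(bid) < cfg.protected_levels:
        return False
    if centerline_length(tree.branch(bid)) < cfg.min_cut_space:
        return False
    return True


def _collapse(tree: VesselTree, bid: int, label: str) -> tuple[VesselTree, tuple[int, ...], int]:
    """Replace branch ``bid``'s leaf children by making ``bid`` an outlet."""
    kids = tree.children(bid)
    member_ids = tuple(sorted(k.outlet_id for k in kids))
    tpp_sum = sum(k.tpp for k in kids)
    remove = {k.branch_id for k in kids}
    new_branches = [b.copy() for b in tree.branches if b.branch_id not in remove]
    for b in new_branches:
        if b.branch_id == bid:
            b.outlet_id = min(member_ids)
            b.tpp = tpp_sum
            b.tissue_label = label
    out = VesselTree(
        branches=new_branches,
        root_branch_id=tree.root_branch_id,
        gravity_direction=tree.gravity_direction.copy(),
    )
    return out, member_ids, min(member_ids)


def _extend_short_leaves(
    tree: VesselTree, touched_outlets: set[int], cfg: TruncationConfig, report: TruncationReport
) -> VesselTree:
    for leaf in list(tree.leaves):
        if leaf.outlet_id in touched_outlets and centerline_length(leaf) < cfg.short_outlet_limit:
            tree = extend_outlet(tree, leaf.branch_id, cfg.extension_target)
            report.extended_outlets.append(leaf.outlet_id)
    return tree


def _check_tpp_coverage(tree: VesselTree, tpp: PerfusionMap) -> None:
    missing = [o for o in tree.outlet_ids if o not in tpp.tpp_by_outlet]
    if missing:
        raise ValueError(f"missing TPP for outlets {missing}")


def prune_low_tpp(
    tree: VesselTree, tpp: PerfusionMap, cfg: TruncationConfig | None = None
) -> tuple[VesselTree, TruncationReport]:
    """Step 1: prune distal junctions containing low-TPP outlets.

    Returns a new tree and a report. The input tree is not modified.
    """
    cfg = cfg or TruncationConfig()
    _check_tpp_coverage(tree, tpp)
    work = tree.copy()
    for leaf in work.leaves:
        leaf.tpp = tpp.tpp_by_outlet[leaf.outlet_id]
    _seed_labels(work, cfg.tpp_threshold)

    report = TruncationReport(outlets_before=work.n_outlets)
    merged: dict[int, set[int]] = {}
    touched: set[int] = set()
    changed = True
    while changed:
        changed = False
        for bid in _terminal_junctions(work):
            kids = work.children(bid)
            # the trigger is a low-but-nonzero TPP outlet; pure healthy
            # (TPP = 0) junctions are step 2's same-tissue case
            if not any(0.0 < k.tpp <= cfg.tpp_threshold for k in kids):
                continue
            if not _collapsible(work, bid, cfg):
                continue
            group_tpp = sum(k.tpp for k in kids)
            label = TUMOR if group_tpp > cfg.tpp_threshold else HEALTHY
            members = set()
            for k in kids:
                members |= merged.pop(k.outlet_id, {k.outlet_id})
            work, _, new_oid = _collapse(work, bid, label)
            merged[new_oid] = members
            touched.add(new_oid)
            report.labels_assigned[new_oid] = label
            changed = True
            break  # topology changed; recompute terminal junctions

    work = _extend_short_leaves(work, touched, cfg, report)
    for oid in sorted(set(work.outlet_ids)):
        members = tuple(sorted(merged.get(oid, {oid})))
        report.merged_groups.append((oid, members))
    report.outlets_after = work.n_outlets
    return work, report


def merge_perfusion_map(tpp: PerfusionMap, report: TruncationReport) -> PerfusionMap:
    """Fold a perfusion map through a truncation report (TPPs sum over members)."""
    out_tpp = {}
    out_ml = {}
    for rid, members in report.merged_groups:
        out_tpp[rid] = sum(tpp.tpp_by_outlet[m] for m in members)
        out_ml[rid] = sum(tpp.perfused_ml_by_outlet.get(m, 0.0) for m in members)
    return PerfusionMap(
        tpp_by_outlet=out_tpp,
        tumor_volume_ml=tpp.tumor_volume_ml,
        perfused_ml_by_outlet=out_ml,
    )


def compose_reports(first: TruncationReport, second: TruncationReport) -> TruncationReport:
    """Chain two truncation steps into one original->final member mapping."""
    first_members = first.members_by_outlet
    out = TruncationReport(
        outlets_before=first.outlets_before,
        outlets_after=second.outlets_after,
        extended_outlets=first.extended_outlets + second.extended_outlets,
        labels_assigned={**first.labels_assigned, **second.labels_assigned},
    )
    for rid, mids in second.merged_groups:
        members: set[int] = set()
        for m in mids:
            members |= set(first_members.get(m, (m,)))
        out.merged_groups.append((rid, tuple(sorted(members))))
    return out


def merge_same_tissue(
    tree: VesselTree,
    tpp: PerfusionMap,
    bc=None,
    cfg: TruncationConfig | None = None,
) -> tuple[VesselTree, TruncationReport]:
    """Step 2: merge sibling leaves perfusing the same tissue type.

    ``bc`` (a :class:`hepatrunc.hemodynamics.FlowBC` keyed by the *input*
    tree's outlet ids — fold it through the step-1 report with
    :func:`hepatrunc.hemodynamics.merge_flow_bc` first) supplies the
    tumor-flow majority rule for residual low-TPP leaves; if omitted,
    residual unassigned leaves raise.
    """
    cfg = cfg or TruncationConfig()
    _check_tpp_coverage(tree, tpp)
    work = tree.copy()
    for leaf in work.leaves:
        leaf.tpp = tpp.tpp_by_outlet[leaf.outlet_id]
    _seed_labels(work, cfg.tpp_threshold)

    report = TruncationReport(outlets_before=work.n_outlets)
    merged: dict[int, set[int]] = {}
    touched: set[int] = set()
    changed = True
    while changed:
        changed = False
        for bid in _terminal_junctions(work):
            kids = work.children(bid)
            labels = {k.tissue_label for k in kids}
            has_low = any(0.0 < k.tpp <= cfg.tpp_threshold for k in kids)
            same_tissue = labels <= {HEALTHY} or labels <= {TUMOR}
            if not (same_tissue or has_low):
                continue
            if not _collapsible(work, bid, cfg):
                continue
            if same_tissue and not has_low:
                label = kids[0].tissue_label
            else:
                group_tpp = sum(k.tpp for k in kids)
                label = TUMOR if group_tpp > cfg.tpp_threshold else HEALTHY
            members = set()
            for k in kids:
                members |= merged.pop(k.outlet_id, {k.outlet_id})
            work, _, new_oid = _collapse(work, bid, label)
            merged[new_oid] = members
            touched.add(new_oid)
            report.labels_assigned[new_oid] = label
            changed = True
            break

    # residual low-TPP leaves that could not be pruned: flow-majority rule
    for leaf in work.leaves:
        if leaf.tissue_label == UNASSIGNED:
            if bc is None:
                raise ValueError(
                    f"leaf outlet {leaf.outlet_id} needs the flow-majority rule "
                    "but no flow boundary conditions were given"
                )
            members = merged.get(leaf.outlet_id, {leaf.outlet_id})
            q_t = sum(bc.Q_t.get(m, 0.0) for m in members)
            q_b = sum(bc.Q_b.get(m, 0.0) for m in members)
            if q_b <= 0:
                raise ValueError(f"outlet {leaf.outlet_id} has zero total flow")
            share = 100.0 * q_t / q_b
            leaf.tissue_label = TUMOR if share > cfg.tumor_flow_majority else HEALTHY
            report.labels_assigned[leaf.outlet_id] = leaf.tissue_label

    work = _extend_short_leaves(work, touched, cfg, report)
    for oid in sorted(set(work.outlet_ids)):
        members = tuple(sorted(merged.get(oid, {oid})))
        report.merged_groups.append((oid, members))
    report.outlets_after = work.n_outlets
    return work, report
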