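"""Arterial tree data model, validation, JSON I/O and synthetic generation.

A :class:`VesselTree` is a rooted directed tree of :class:`Branch` objects.
Each branch carries a 3-D centerline polyline and a single representative
diameter; leaf branches carry outlet ids. All lengths are in meters
internally — converters to mm are applied only at I/O boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

HEALTHY = "healthy"
TUMOR = "tumor"
UNASSIGNED = "unassigned"

_TISSUE_LABELS = (HEALTHY, TUMOR, UNASSIGNED)


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class TreeParseError(ValueError):
    """Raised when a tree file does not conform to the JSON schema."""


@dataclass
class Branch:
    """One vessel segment between two junctions (or junction and outlet).

    Parameters
    ----------
    branch_id : int
        Unique integer id.
    parent_id : int or None
        Id of the feeding branch; ``None`` for the root.
    centerline : (n, 3) array
        Ordered polyline in meters, ``n >= 2``, consecutive points distinct.
    diameter : float
        Representative lumen diameter [m], > 0.
    outlet_id : int or None
        Outlet label for leaf branches.
    tissue_label : str
        One of ``healthy``, ``tumor``, ``unassigned``.
    tpp : float
        Tumor perfusion percentage in [0, 100].
    was_extended : bool
        Set when the outlet was artificially extruded.
    """

    branch_id: int
    parent_id: int | None
    centerline: np.ndarray
    diameter: float
    outlet_id: int | None = None
    tissue_label: str = UNASSIGNED
    tpp: float = 0.0
    was_extended: bool = False

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise TreeValidationError(
                f"branch {self.branch_id}: centerline must be (n, 3), "
                f"got {self.centerline.shape}"
            )
        if self.centerline.shape[0] < 2:
            raise TreeValidationError(
                f"branch {self.branch_id}: centerline needs >= 2 points"
            )
        seg = np.diff(self.centerline, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise TreeValidationError(
                f"branch {self.branch_id}: consecutive centerline points coincide"
            )
        if not self.diameter > 0:
            raise TreeValidationError(
                f"branch {self.branch_id}: diameter must be > 0, got {self.diameter}"
            )
        if not (0.0 <= self.tpp <= 100.0):
            raise TreeValidationError(
                f"branch {self.branch_id}: tpp must be in [0, 100], got {self.tpp}"
            )
        if self.tissue_label not in _TISSUE_LABELS:
            raise TreeValidationError(
                f"branch {self.branch_id}: unknown tissue_label {self.tissue_label!r}"
            )

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    def copy(self) -> "Branch":
        return replace(self, centerline=self.centerline.copy())


def centerline_length(branch: Branch) -> float:
    """Total polyline length of a branch centerline [m]."""
    seg = np.diff(branch.centerline, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


@dataclass
class VesselTree:
    """Rooted directed arterial tree.

    Invariants (checked by :meth:`validate`): single root, no cycles, every
    non-root branch has exactly one parent, junctions are bifurcations or
    trifurcations, leaves carry unique outlet ids.
    """

    branches: list[Branch]
    root_branch_id: int
    gravity_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0])
    )

    def __post_init__(self) -> None:
        self.gravity_direction = np.asarray(self.gravity_direction, dtype=float)
        self.validate()

    # -- structure -------------------------------------------------------

    def branch(self, branch_id: int) -> Branch:
        return self._by_id[branch_id]

    def children(self, branch_id: int) -> list[Branch]:
        return [self._by_id[c] for c in self._children.get(branch_id, ())]

    @property
    def root(self) -> Branch:
        return self._by_id[self.root_branch_id]

    @property
    def leaves(self) -> list[Branch]:
        return [b for b in self.branches if not self._children.get(b.branch_id)]

    @property
    def outlet_ids(self) -> list[int]:
        return sorted(b.outlet_id for b in self.leaves)

    @property
    def n_outlets(self) -> int:
        return len(self.leaves)

    def outlet_branch(self, outlet_id: int) -> Branch:
        for b in self.leaves:
            if b.outlet_id == outlet_id:
                return b
        raise KeyError(f"no leaf with outlet id {outlet_id}")

    def path_to_root(self, branch_id: int) -> list[int]:
        """Branch ids from ``branch_id`` up to and including the root."""
        path = [branch_id]
        while self._by_id[path[-1]].parent_id is not None:
            path.append(self._by_id[path[-1]].parent_id)
        return path

    def junction_level(self, branch_id: int) -> int:
        """Number of junctions on the root path strictly above this branch.

        The junction at the distal end of the root branch is level 0; the
        next generation of junctions is level 1, and so on.
        """
        level = 0
        for bid in self.path_to_root(branch_id)[1:]:
            if len(self._children.get(bid, ())) >= 2:
                level += 1
        return level

    def copy(self) -> "VesselTree":
        return VesselTree(
            branches=[b.copy() for b in self.branches],
            root_branch_id=self.root_branch_id,
            gravity_direction=self.gravity_direction.copy(),
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        ids = [b.branch_id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise TreeValidationError("duplicate branch ids")
        self._by_id = {b.branch_id: b for b in self.branches}
        if self.root_branch_id not in self._by_id:
            raise TreeValidationError(f"root branch {self.root_branch_id} not present")

        g = nx.DiGraph()
        g.add_nodes_from(ids)
        roots = []
        for b in self.branches:
            if b.parent_id is None:
                roots.append(b.branch_id)
            else:
                if b.parent_id not in self._by_id:
                    raise TreeValidationError(
                        f"branch {b.branch_id} references missing parent {b.parent_id}"
                    )
                g.add_edge(b.parent_id, b.branch_id)
        if roots != [self.root_branch_id] and set(roots) != {self.root_branch_id}:
            raise TreeValidationError(
                f"expected a single root {self.root_branch_id}, found roots {roots}"
            )
        if not nx.is_directed_acyclic_graph(g):
            raise TreeValidationError("tree topology contains a cycle")
        if not nx.is_arborescence(g):
            raise TreeValidationError("topology is not a rooted tree")

        self._children: dict[int, tuple[int, ...]] = {}
        for b in self.branches:
            kids = tuple(sorted(g.successors(b.branch_id)))
            self._children[b.branch_id] = kids
            if len(kids) == 1 or len(kids) > 3:
                raise TreeValidationError(
                    f"branch {b.branch_id} has {len(kids)} daughters; "
                    "junctions must be bifurcations or trifurcations"
                )

        outlet_ids = []
        for b in self.branches:
            if not self._children[b.branch_id]:
                if b.outlet_id is None:
                    raise TreeValidationError(
                        f"leaf branch {b.branch_id} has no outlet id"
                    )
                outlet_ids.append(b.outlet_id)
            elif b.outlet_id is not None:
                raise TreeValidationError(
                    f"internal branch {b.branch_id} carries outlet id {b.outlet_id}"
                )
        if len(set(outlet_ids)) != len(outlet_ids):
            raise TreeValidationError("outlet ids are not unique")

        gnorm = np.linalg.norm(self.gravity_direction)
        if not math.isclose(gnorm, 1.0, rel_tol=1e-6):
            raise TreeValidationError("gravity_direction must be a unit vector")


# -- I/O -----------------------------------------------------------------


def save_tree(tree: VesselTree, path) -> None:
    """Write a tree to the JSON schema (units: meters)."""
    doc = {
        "root": tree.root_branch_id,
        "gravity": [float(x) for x in tree.gravity_direction],
        "branches": [
            {
                "id": b.branch_id,
                "parent": b.parent_id,
                "centerline": [[float(x) for x in p] for p in b.centerline],
                "diameter": float(b.diameter),
                "outlet_id": b.outlet_id,
                "tissue_label": b.tissue_label,
                "tpp": float(b.tpp),
                "was_extended": bool(b.was_extended),
            }
            for b in tree.branches
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_tree(path) -> VesselTree:
    """Load and validate a tree from the JSON schema."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TreeParseError(f"not valid JSON: {exc}") from exc
    for key in ("root", "branches"):
        if key not in doc:
            raise TreeParseError(f"missing top-level field {key!r}")
    branches = []
    for i, bd in enumerate(doc["branches"]):
        for key in ("id", "centerline", "diameter"):
            if key not in bd:
                raise TreeParseError(f"branch #{i}: missing field {key!r}")
        try:
            branches.append(
                Branch(
                    branch_id=int(bd["id"]),
                    parent_id=None if bd.get("parent") is None else int(bd["parent"]),
                    centerline=np.asarray(bd["centerline"], dtype=float),
                    diameter=float(bd["diameter"]),
                    outlet_id=None
                    if bd.get("outlet_id") is None
                    else int(bd["outlet_id"]),
                    tissue_label=bd.get("tissue_label", UNASSIGNED),
                    tpp=float(bd.get("tpp", 0.0)),
                    was_extended=bool(bd.get("was_extended", False)),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, TreeValidationError):
                raise
            raise TreeParseError(f"branch #{i}: {exc}") from exc
    return VesselTree(
        branches=branches,
        root_branch_id=int(doc["root"]),
        gravity_direction=np.asarray(doc.get("gravity", [0.0, 0.0, -1.0]), float),
    )


# -- geometry edits ------------------------------------------------------


def extend_outlet(
    tree: VesselTree, branch_id: int, target_length: float
) -> VesselTree:
    """Extrude a leaf branch along its terminal tangent to ``target_length``.

    Returns a new tree; the diameter and all other branches are untouched.
    A leaf already at or beyond the target is returned unchanged.
    """
    out = tree.copy()
    b = out.branch(branch_id)
    if out.children(branch_id):
        raise ValueError(f"branch {branch_id} is not a leaf; cannot extend")
    length = centerline_length(b)
    if length >= target_length - 1e-12:
        import warnings

        warnings.warn(
            f"branch {branch_id} already has length {length:.4g} m "
            f">= target {target_length:.4g} m; no-op"
        )
        return out
    tangent = b.centerline[-1] - b.centerline[-2]
    tangent = tangent / np.linalg.norm(tangent)
    tip = b.centerline[-1] + tangent * (target_length - length)
    b.centerline = np.vstack([b.centerline, tip])
    b.was_extended = True
    out.validate()
    return out


# -- synthetic generation ------------------------------------------------


@dataclass
class SyntheticTreeSpec:
    """Recipe for a deterministic synthetic arterial tree.

    ``diameter_rule`` is either ``("murray",)`` — daughters get
    ``d_parent * n_daughters**(-1/3)`` (Murray's cube law for symmetric
    splits) — or ``("ratio", r)`` with a fixed parent/daughter ratio.
    ``segment_assignment`` maps outlet id -> Couinaud segment name; if
    ``None``, outlets are distributed over the eight segments contiguously.
    """

    n_outlets: int = 8
    root_diameter: float = 4.0e-3
    root_length: float = 30.0e-3
    branch_length: float = 20.0e-3
    length_decay: float = 0.85
    half_angle: float = 0.5  # radians, mean daughter opening half-angle
    allow_trifurcations: bool = False
    diameter_rule: tuple = ("murray",)
    segment_assignment: Mapping[int, str] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outlets < 1:
            raise ValueError("n_outlets must be >= 1")


_SEGMENTS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def default_segment_assignment(outlet_ids: Sequence[int]) -> dict[int, str]:
    """Distribute outlets over the eight Couinaud segments contiguously."""
    n = len(outlet_ids)
    nseg = min(8, n)
    out = {}
    for i, oid in enumerate(sorted(outlet_ids)):
        out[oid] = _SEGMENTS[min(i * nseg // n, nseg - 1)]
    return out

def _daughter_diameter(d_parent: float, n_daughters: int, rule: tuple) -> float:
    if rule[0] == "murray":
        return d_parent * n_daughters ** (-1.0 / 3.0)
    if rule[0] == "ratio":
        return d_parent * float(rule[1])
    raise ValueError(f"unknown diameter rule {rule!r}")


def generate_synthetic_tree(spec: SyntheticTreeSpec) -> VesselTree:
    """Grow a deterministic tree with exactly ``spec.n_outlets`` outlets.

    Growth repeatedly splits the leaf closest to the root (breadth-first)
    into two (or, when allowed and needed, three) daughters whose directions
    fan out around the parent tangent with a seeded random azimuth. Leaf
    order and the RNG stream are fixed, so generation is reproducible.
    """
    rng = np.random.default_rng(spec.rng_seed)
    next_id = [0]

    def new_id() -> int:
        next_id[0] += 1
        return next_id[0]

    root = Branch(
        branch_id=new_id(),
        parent_id=None,
        centerline=np.array([[0.0, 0.0, 0.0], [spec.root_length, 0.0, 0.0]]),
        diameter=spec.root_diameter,
    )
    branches = [root]
    children: dict[int, list[int]] = {root.branch_id: []}
    depth = {root.branch_id: 0}

    # leaves kept in (depth, id) order so the shallowest leaf splits first
    import heapq

    frontier: list[tuple[int, int]] = [(0, root.branch_id)]
    n_leaves = 1
    while n_leaves < spec.n_outlets:
        d, bid = heapq.heappop(frontier)
        parent = next(b for b in branches if b.branch_id == bid)
        deficit = spec.n_outlets - n_leaves
        arity = 3 if (spec.allow_trifurcations and deficit >= 2 and rng.random() < 0.25) else 2
        arity = min(arity, deficit + 1)
        tangent = parent.centerline[-1] - parent.centerline[-2]
        tangent = tangent / np.linalg.norm(tangent)
        # orthonormal frame around the tangent
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, tangent)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(tangent, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(tangent, e1)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        length = spec.branch_length * spec.length_decay ** d
        d_child = _daughter_diameter(parent.diameter, arity, spec.diameter_rule)
        for k in range(arity):
            phi = phi0 + 2.0 * np.pi * k / arity
            ang = spec.half_angle * (0.8 + 0.4 * rng.random())
            direction = (
                np.cos(ang) * tangent
                + np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2)
            )
            direction /= np.linalg.norm(direction)
            start = parent.centerline[-1]
            child = Branch(
                branch_id=new_id(),
                parent_id=parent.branch_id,
                centerline=np.array([start, start + direction * length]),
                diameter=d_child,
            )
            branches.append(child)
            children.setdefault(parent.branch_id, []).append(child.branch_id)
            children[child.branch_id] = []
            depth[child.branch_id] = d + 1
            heapq.heappush(frontier, (d + 1, child.branch_id))
        n_leaves += arity - 1

    # assign contiguous outlet ids to leaves in id order
    oid = 0
    for b in branches:
        if not children.get(b.branch_id):
            oid += 1
            b.outlet_id = oid
    tree = VesselTree(branches=branches, root_branch_id=root.branch_id)
    if tree.n_outlets != spec.n_outlets:
        raise RuntimeError(
            f"generator produced {tree.n_outlets} outlets, wanted {spec.n_outlets}"
        )
    return tree


def trees_structurally_equal(a: VesselTree, b: VesselTree) -> bool:
    """Field-wise structural equality of two trees."""
    if a.root_branch_id != b.root_branch_id:
        return False
    if not np.allclose(a.gravity_direction, b.gravity_direction):
        return False
    if len(a.branches) != len(b.branches):
        return False
    bb = {x.branch_id: x for x in b.branches}
    for ba in a.branches:
        if ba.branch_id not in bb:
            return False
        other = bb[ba.branch_id]
        if (
            ba.parent_id != other.parent_id
            or ba.outlet_id != other.outlet_id
            or ba.tissue_label != other.tissue_label
            or ba.was_extended != other.was_extended
            or not math.isclose(ba.diameter, other.diameter, rel_tol=1e-12)
            or not math.isclose(ba.tpp, other.tpp, rel_tol=1e-12, abs_tol=1e-12)
            or ba.centerline.shape != other.centerline.shape
            or not np.allclose(ba.centerline, other.centerline, atol=1e-15)
        ):
            return False
    return True
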