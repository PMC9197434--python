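import numpy as np
import pytest

from hepatrunc.vascular import Branch, VesselTree


def straight(points):
    return np.asarray(points, dtype=float)


@pytest.fixture
def bifurcation_tree():
    """Smallest valid tree: root splitting into two outlets."""
    mm = 1e-3
    branches = [
        Branch(1, None, straight([[0, 0, 0], [20 * mm, 0, 0]]), 4 * mm),
        Branch(
            2, 1, straight([[20 * mm, 0, 0], [35 * mm, 10 * mm, 0]]), 3 * mm, outlet_id=1
        ),
        Branch(
            3, 1, straight([[20 * mm, 0, 0], [35 * mm, -10 * mm, 0]]), 3 * mm, outlet_id=2
        ),
    ]
    return VesselTree(branches=branches, root_branch_id=1)


def nested_tree(leaf_tpps, protected_levels_deep=True):
    """Three-level binary tree with 4 outlets and given leaf TPPs.

    Root -> (A, B); A -> (o1, o2); B -> (o3, o4). The junctions at A and B
    are level 1, so with protected_levels=1 they are collapsible.
    """
    mm = 1e-3
    b = [
        Branch(1, None, straight([[0, 0, 0], [20 * mm, 0, 0]]), 4 * mm),
        Branch(2, 1, straight([[20 * mm, 0, 0], [40 * mm, 8 * mm, 0]]), 3 * mm),
        Branch(3, 1, straight([[20 * mm, 0, 0], [40 * mm, -8 * mm, 0]]), 3 * mm),
        Branch(4, 2, straight([[40 * mm, 8 * mm, 0], [60 * mm, 14 * mm, 0]]), 2 * mm, outlet_id=1),
        Branch(5, 2, straight([[40 * mm, 8 * mm, 0], [60 * mm, 2 * mm, 0]]), 2 * mm, outlet_id=2),
        Branch(6, 3, straight([[40 * mm, -8 * mm, 0], [60 * mm, -2 * mm, 0]]), 2 * mm, outlet_id=3),
        Branch(7, 3, straight([[40 * mm, -8 * mm, 0], [60 * mm, -14 * mm, 0]]), 2 * mm, outlet_id=4),
    ]
    tree = VesselTree(branches=b, root_branch_id=1)
    for leaf, tpp in zip(tree.leaves, [leaf_tpps[o] for o in sorted(leaf_tpps)]):
        leaf.tpp = tpp
    return tree
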