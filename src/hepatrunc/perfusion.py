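"""Voxel region-growing perfusion territories and tumor perfusion percentages.

Each outlet's terminal centerline points seed a synchronous 6-connected
wavefront; all wavefronts advance one voxel layer per iteration until every
tumor voxel is claimed by exactly one outlet. The tumor perfusion percentage
(TPP) of an outlet is the share of tumor voxels it claims. Growth passes
through non-tumor voxels (seed voxels are vessel ends, generally outside the
mask); only tumor voxels count toward TPP. Ties within one iteration go to
the lowest outlet id, which makes labeling deterministic and independent of
seed ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from hepatrunc.vascular import VesselTree

UNLABELED = -1


class PerfusionError(ValueError):
    pass


@dataclass
class VoxelGrid:
    """Cubic-voxel volume holding the tumor mask and outlet labels.

    Voxels are half-open cells ``[origin + i*h, origin + (i+1)*h)`` with a
    single edge length ``h`` [m]; indexing is 0-based.
    """

    shape: tuple[int, int, int]
    edge_length: float
    origin: np.ndarray
    tumor_mask: np.ndarray
    label_volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.origin = np.asarray(self.origin, dtype=float)
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        if self.tumor_mask.shape != self.shape:
            raise PerfusionError(
                f"tumor_mask shape {self.tumor_mask.shape} != grid shape {self.shape}"
            )
        if self.label_volume is None:
            self.label_volume = np.full(self.shape, UNLABELED, dtype=np.int32)
        else:
            self.label_volume = np.asarray(self.label_volume, dtype=np.int32)
            if self.label_volume.shape != self.shape:
                raise PerfusionError("label_volume shape mismatch")
        if not self.edge_length > 0:
            raise PerfusionError("edge_length must be > 0")

    @property
    def voxel_volume_m3(self) -> float:
        return float(self.edge_length) ** 3

    def point_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Voxel indices of points [m]; points outside the grid get -1 rows."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx = np.floor((pts - self.origin) / self.edge_length).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        idx[~inside] = -1
        return idx

    def to_nifti(self) -> "nib.Nifti1Image":
        affine = np.eye(4)
        affine[:3, :3] *= self.edge_length
        affine[:3, 3] = self.origin
        vol = np.where(self.tumor_mask, 1, 0).astype(np.int16)
        return nib.Nifti1Image(vol, affine)

    @classmethod
    def from_nifti(cls, img_or_path) -> "VoxelGrid":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(img_or_path)
        vox = img.header.get_zooms()[:3]
        if not np.allclose(vox, vox[0], rtol=1e-6):
            raise PerfusionError("grid voxels must be cubic")
        data = np.asarray(img.dataobj)
        return cls(
            shape=data.shape,
            edge_length=float(vox[0]),
            origin=np.asarray(img.affine[:3, 3], float),
            tumor_mask=data > 0,
        )


@dataclass
class SeedSet:
    """Per-outlet voxel seed indices."""

    seeds_by_outlet: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.seeds_by_outlet = {
            int(k): np.atleast_2d(np.asarray(v, dtype=int))
            for k, v in self.seeds_by_outlet.items()
        }
        for oid, s in self.seeds_by_outlet.items():
            if s.shape[0] == 0:
                raise PerfusionError(f"outlet {oid} has no seed voxels")


@dataclass
class PerfusionMap:
    """Per-outlet tumor perfusion percentages and volumes."""

    tpp_by_outlet: dict[int, float]
    tumor_volume_ml: float
    perfused_ml_by_outlet: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.tpp_by_outlet.values())
        if abs(total - 100.0) > 1e-6:
            raise PerfusionError(f"TPPs must sum to 100%, got {total}")


def extract_seeds(tree: VesselTree, grid: VoxelGrid) -> SeedSet:
    """Seed voxels: the voxels containing each terminal segment's centerline.

    The terminal segment is the leaf branch between the final junction and
    the outlet surface; the junction point itself is excluded (sibling
    leaves share it). Seeds of distinct outlets may not share a voxel.
    """
    seeds: dict[int, np.ndarray] = {}
    claimed: dict[tuple[int, int, int], int] = {}
    for leaf in tree.leaves:
        pts = leaf.centerline[1:] if leaf.parent_id is not None else leaf.centerline
        idx = grid.point_to_index(pts)
        idx = idx[np.all(idx >= 0, axis=1)]
        if idx.shape[0] == 0:
            raise PerfusionError(
                f"outlet {leaf.outlet_id}: no centerline point inside the grid"
            )
        uniq = np.unique(idx, axis=0)
        for v in map(tuple, uniq):
            if v in claimed:
                raise PerfusionError(
                    f"outlets {claimed[v]} and {leaf.outlet_id} share seed voxel {v}"
                )
            claimed[v] = leaf.outlet_id
        seeds[leaf.outlet_id] = uniq
    return SeedSet(seeds)


def region_grow(grid: VoxelGrid, seeds: SeedSet) -> VoxelGrid:
    """Synchronous multi-source breadth-first growth over the whole grid.

    All labels advance one 6-connected layer per iteration; a voxel reached
    by several labels in the same iteration takes the lowest outlet id.
    Terminates when every tumor voxel is labeled.
    """
    label = np.full(grid.shape, UNLABELED, dtype=np.int32)
    for oid in sorted(seeds.seeds_by_outlet):
        s = seeds.seeds_by_outlet[oid]
        label[s[:, 0], s[:, 1], s[:, 2]] = oid

    big = np.iinfo(np.int32).max
    while True:
        if np.all(label[grid.tumor_mask] != UNLABELED):
            break
        # candidate label per voxel: minimum labeled value over 6-neighbors
        cand = np.full(grid.shape, big, dtype=np.int64)
        lab = np.where(label == UNLABELED, big, label).astype(np.int64)
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(1, None)
            hi[axis] = slice(None, -1)
            lo, hi = tuple(lo), tuple(hi)
            np.minimum(cand[lo], lab[hi], out=cand[lo])  # from the -axis side
            np.minimum(cand[hi], lab[lo], out=cand[hi])  # from the +axis side
        newly = (label == UNLABELED) & (cand < big)
        if not np.any(newly):
            missing = int(np.count_nonzero(label[grid.tumor_mask] == UNLABELED))
            raise PerfusionError(
                f"{missing} tumor voxels unreachable from any seed"
            )
        label[newly] = cand[newly].astype(np.int32)

    out = VoxelGrid(
        shape=grid.shape,
        edge_length=grid.edge_length,
        origin=grid.origin,
        tumor_mask=grid.tumor_mask,
        label_volume=label,
    )
    return out


def compute_tpp(grid: VoxelGrid, tree: VesselTree | None = None) -> PerfusionMap:
    """Tumor perfusion percentage per outlet from a labeled grid.

    ``tpp(outlet) = 100 * (# tumor voxels with that label) / (# tumor voxels)``.
    When a tree is given, TPPs are written onto its leaf branches.
    """
    if not np.any(grid.tumor_mask):
        raise PerfusionError("tumor mask is empty")
    labels = grid.label_volume[grid.tumor_mask]
    if np.any(labels == UNLABELED):
        raise PerfusionError("tumor voxels remain unlabeled; run region_grow first")
    n_tumor = labels.size
    vox_ml = grid.voxel_volume_m3 * 1e6  # m^3 -> ml
    uniq, counts = np.unique(labels, return_counts=True)
    tpp = {int(o): 100.0 * c / n_tumor for o, c in zip(uniq, counts)}
    perfused = {int(o): float(c) * vox_ml for o, c in zip(uniq, counts)}
    if tree is not None:
        for leaf in tree.leaves:
            leaf.tpp = tpp.get(leaf.outlet_id, 0.0)
            tpp.setdefault(leaf.outlet_id, 0.0)
            perfused.setdefault(leaf.outlet_id, 0.0)
    return PerfusionMap(
        tpp_by_outlet=tpp,
        tumor_volume_ml=n_tumor * vox_ml,
        perfused_ml_by_outlet=perfused,
    )


def assert_partition(grid: VoxelGrid) -> None:
    """Tumor voxels must be exactly singly labeled (partition property)."""
    labels = grid.label_volume[grid.tumor_mask]
    if np.any(labels == UNLABELED):
        raise AssertionError("unlabeled tumor voxel found")
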