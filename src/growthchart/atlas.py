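"""Anatomical containers: labeled volumes and the region ontology.

A :class:`LabelVolume` is a 3D integer grid of anatomical region ids over a
physical voxel lattice (world coordinates in micrometres), the volumetric
ground truth for counting and volumetry.  An :class:`Ontology` is the
id/acronym/parent hierarchy used to roll leaf-region statistics up to parent
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["LabelVolume", "Ontology"]


@dataclass(frozen=True)
class LabelVolume:
    """3D grid of non-negative integer region ids with physical voxel size.

    Parameters
    ----------
    grid
        Integer array of shape ``(ni, nj, nk)``; 0 is background.
    voxel_size_um
        Physical edge length of a voxel along each axis, in micrometres.
    origin_um
        World coordinate of the corner of voxel ``(0, 0, 0)``.
    """

    grid: np.ndarray
    voxel_size_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise ValueError(f"grid must be 3D with all dims >= 1, got shape {grid.shape}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError(f"grid must be an integer array, got dtype {grid.dtype}")
        if grid.min() < 0:
            raise ValueError("region ids must be >= 0")
        if len(self.voxel_size_um) != 3 or any(s <= 0 for s in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be three positive numbers, got {self.voxel_size_um}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "voxel_size_um", tuple(float(s) for s in self.voxel_size_um))
        object.__setattr__(self, "origin_um", tuple(float(s) for s in self.origin_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (1 mm^3 = 1e9 um^3)."""
        sx, sy, sz = self.voxel_size_um
        return sx * sy * sz * 1e-9

    def region_ids(self) -> np.ndarray:
        """Sorted nonzero ids present in the grid."""
        ids = np.unique(self.grid)
        return ids[ids > 0]

    def voxel_counts(self) -> pd.Series:
        """Voxel count per nonzero id (index = region_id)."""
        counts = np.bincount(self.grid.ravel())
        ids = np.nonzero(counts)[0]
        s = pd.Series(counts[ids], index=pd.Index(ids, name="region_id"), name="n_voxels")
        return s[s.index > 0]

    # -- I/O ---------------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        """Write as NIfTI with the voxel size in the header zooms (um).

        Gzipped output is written with a zeroed gzip timestamp so repeated
        runs are byte-identical.
        """
        affine = np.diag([*self.voxel_size_um, 1.0])
        affine[:3, 3] = self.origin_um
        img = nib.Nifti1Image(self.grid.astype(np.int32), affine)
        img.header.set_zooms(self.voxel_size_um)
        if str(path).endswith(".gz"):
            import gzip

            with open(path, "wb") as fh, gzip.GzipFile(
                filename="", fileobj=fh, mode="wb", mtime=0
            ) as gz:
                gz.write(img.to_bytes())
        else:
            nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "LabelVolume":
        img = nib.load(path)
        grid = np.asarray(img.dataobj).astype(np.int32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(grid=grid, voxel_size_um=zooms, origin_um=origin)


class Ontology:
    """Anatomical hierarchy: unique ids, one root, acyclic parent links.

    Backed by a DataFrame with columns ``id``, ``acronym``, ``name``,
    ``parent_id`` (NaN / empty for the root).
    """

    def __init__(self, nodes: pd.DataFrame):
        required = {"id", "acronym", "name", "parent_id"}
        missing = required - set(nodes.columns)
        if missing:
            raise ValueError(f"ontology table missing columns: {sorted(missing)}")
        nodes = nodes.copy()
        nodes["id"] = nodes["id"].astype(int)
        nodes["parent_id"] = pd.array(
            [None if pd.isna(p) else int(p) for p in nodes["parent_id"]], dtype="Int64"
        )
        if nodes["id"].duplicated().any():
            dups = nodes.loc[nodes["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate ontology ids: {dups}")
        roots = nodes.loc[nodes["parent_id"].isna(), "id"].tolist()
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        known = set(nodes["id"])
        bad_parents = set(nodes["parent_id"].dropna()) - known
        if bad_parents:
            raise ValueError(f"parent ids not in ontology: {sorted(bad_parents)}")
        self.nodes = nodes.reset_index(drop=True)
        self._parent = {
            int(r.id): (None if pd.isna(r.parent_id) else int(r.parent_id))
            for r in nodes.itertuples()
        }
        self._children: dict[int, list[int]] = {int(i): [] for i in nodes["id"]}
        for cid, pid in self._parent.items():
            if pid is not None:
                self._children[pid].append(cid)
        self.root = roots[0]
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen_global: set[int] = set()
        for start in self._parent:
            node, trail = start, set()
            while node is not None and node not in seen_global:
                if node in trail:
                    raise ValueError(f"cycle in ontology parent links at id {node}")
                trail.add(node)
                node = self._parent[node]
            seen_global |= trail

    # -- navigation --------------------------------------------------------

    def parent(self, region_id: int) -> int | None:
        return self._parent[int(region_id)]

    def children(self, region_id: int) -> list[int]:
        return list(self._children[int(region_id)])

    def descendants(self, region_id: int) -> list[int]:
        """All ids strictly below ``region_id`` (depth-first)."""
        out: list[int] = []
        stack = list(self._children[int(region_id)])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out

    def depth(self, region_id: int) -> int:
        d, node = 0, self._parent[int(region_id)]
        while node is not None:
            d += 1
            node = self._parent[node]
        return d

    def ids(self) -> list[int]:
        return [int(i) for i in self.nodes["id"]]

    def leaves(self) -> list[int]:
        return [i for i, ch in self._children.items() if not ch]

    def validate_labels(self, volume: LabelVolume) -> None:
        """Every nonzero grid id must be an ontology node."""
        orphans = sorted(set(volume.region_ids().tolist()) - set(self._parent))
        if orphans:
            raise ValueError(f"label ids absent from ontology: {orphans}")

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str) -> None:
        self.nodes.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "Ontology":
        return cls(pd.read_csv(path))
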