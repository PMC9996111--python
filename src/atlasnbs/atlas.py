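"""Probabilistic white-matter bundle atlas and its parcellation.

A bundle atlas summarises, over a reference population, which voxels the
white-matter tract connecting each pair of grey-matter regions occupies.
Each edge (unordered region pair) carries

* a sparse voxel list with an *occupancy probability* in (0, 1] — the
  fraction of the atlas population whose bundle includes that voxel, and
* a *presence fraction* in [0, 1] — the fraction of the population in which
  the bundle exists at all.

Group analyses restrict themselves to edges present in at least 80% of the
population and, within a bundle, to voxels occupied in at least 90% —
both filters are inclusive and exposed here as :func:`consistent_edges`
and :func:`consistent_voxels`.

The on-disk container is a plain directory: ``nodes.tsv`` (parcellation),
``edges.tsv`` (edge index with presence fractions and map filenames) and
one NIfTI probability map per edge. Any atlas exported to this layout —
including a toy atlas from :mod:`atlasnbs.synthetic` — loads identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Bundle",
    "BundleAtlas",
    "ParcellationScheme",
    "consistent_edges",
    "consistent_voxels",
    "load_bundle_atlas",
    "save_bundle_atlas",
]

Edge = tuple[int, int]

NODE_COLUMNS = ["id", "name", "hemisphere", "x", "y", "z"]


class AtlasError(ValueError):
    """Raised when an atlas container or data model violates its invariants."""


def canonical_edge(a: int, b: int) -> Edge:
    """Return the unordered node pair as ``(min, max)``."""
    if a == b:
        raise AtlasError(f"self-loop edge ({a}, {b}) is not a bundle")
    return (a, b) if a < b else (b, a)


@dataclasses.dataclass(frozen=True)
class ParcellationScheme:
    """Grey-matter parcellation: node ids, labels, hemispheres, coordinates (mm)."""

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in NODE_COLUMNS if c not in self.nodes.columns]
        if missing:
            raise AtlasError(f"node table missing columns {missing}")
        ids = self.nodes["id"].to_numpy()
        if len(ids) < 1 or not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise AtlasError("node ids must be unique and contiguous from 0")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def label(self, node: int) -> str:
        return str(self.nodes.set_index("id").loc[node, "name"])

    def coordinates(self, node: int) -> np.ndarray:
        row = self.nodes.set_index("id").loc[node]
        return np.array([row["x"], row["y"], row["z"]], dtype=float)


@dataclasses.dataclass(frozen=True)
class Bundle:
    """One edge's sparse probabilistic map.

    ``voxels`` is an (n, 3) integer array of voxel indices, kept sorted by
    linear index so that reductions over the bundle are order-stable;
    ``occupancy`` the matching per-voxel probabilities in (0, 1].
    """

    voxels: np.ndarray
    occupancy: np.ndarray
    presence: float

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.intp).reshape(-1, 3)
        occ = np.asarray(self.occupancy, dtype=float).reshape(-1)
        if len(vox) != len(occ):
            raise AtlasError("voxel list and occupancy vector lengths differ")
        if len(occ) and (np.any(occ <= 0) or np.any(occ > 1)):
            raise AtlasError("occupancy probabilities must lie in (0, 1]")
        if not 0.0 <= self.presence <= 1.0:
            raise AtlasError("presence fraction must lie in [0, 1]")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_voxels(self) -> int:
        return len(self.occupancy)


@dataclasses.dataclass(frozen=True)
class BundleAtlas:
    """Probabilistic bundle atlas on a common voxel grid.

    Parameters
    ----------
    shape
        Grid dimensions of all probability maps.
    affine
        4x4 voxel-to-world (RAS+) transform shared by all maps.
    bundles
        Mapping from canonical edge ``(a, b)`` with ``a < b`` to :class:`Bundle`.
    parcellation
        The node scheme the edges refer to.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    bundles: dict[Edge, Bundle]
    parcellation: ParcellationScheme

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise AtlasError(f"grid shape must be three positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise AtlasError("affine must be 4x4")
        n = self.parcellation.n_nodes
        for edge, bundle in self.bundles.items():
            a, b = edge
            if not (0 <= a < b < n):
                raise AtlasError(f"edge {edge} not a canonical pair of known nodes (N={n})")
            if bundle.n_voxels and np.any(
                (bundle.voxels < 0) | (bundle.voxels >= np.array(shape))
            ):
                raise AtlasError(f"edge {edge} has voxels outside the grid {shape}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_nodes(self) -> int:
        return self.parcellation.n_nodes

    @property
    def edges(self) -> list[Edge]:
        return sorted(self.bundles)

    def probability_map(self, edge: Edge) -> np.ndarray:
        """Densify one edge's occupancy probabilities onto the grid."""
        bundle = self._bundle(edge)
        vol = np.zeros(self.shape, dtype=float)
        if bundle.n_voxels:
            vol[tuple(bundle.voxels.T)] = bundle.occupancy
        return vol

    def _bundle(self, edge: Edge) -> Bundle:
        edge = canonical_edge(*edge)
        try:
            return self.bundles[edge]
        except KeyError:
            raise AtlasError(f"edge {edge} is not in the atlas") from None


def consistent_edges(atlas: BundleAtlas, presence_threshold: float = 0.8) -> set[Edge]:
    """Edges whose bundle is present in at least ``presence_threshold`` of the population.

    The comparison is inclusive: presence exactly at the threshold is retained.
    """
    if not 0.0 < presence_threshold <= 1.0:
        raise AtlasError("presence threshold must lie in (0, 1]")
    return {
        edge
        for edge, bundle in atlas.bundles.items()
        if bundle.presence >= presence_threshold
    }


def consistent_voxels(
    atlas: BundleAtlas, edge: Edge, occupancy_threshold: float = 0.9
) -> np.ndarray:
    """Voxels of ``edge`` occupied in at least ``occupancy_threshold`` of the population.

    Returns an (k, 3) integer array sorted by linear voxel index (may be
    empty). Inclusive comparison, matching :func:`consistent_edges`.
    """
    if not 0.0 < occupancy_threshold <= 1.0:
        raise AtlasError("occupancy threshold must lie in (0, 1]")
    bundle = atlas._bundle(edge)
    keep = bundle.occupancy >= occupancy_threshold
    vox = bundle.voxels[keep]
    order = np.argsort(np.ravel_multi_index(tuple(vox.T), atlas.shape)) if len(vox) else []
    return vox[order] if len(vox) else vox.reshape(0, 3)


# ---------------------------------------------------------------------------
# container I/O


def save_bundle_atlas(atlas: BundleAtlas, path: str | Path) -> Path:
    """Write the atlas as a container directory (nodes.tsv, edges.tsv, NIfTI maps)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    atlas.parcellation.nodes.to_csv(path / "nodes.tsv", sep="\t", index=False)
    records = []
    for edge in atlas.edges:
        bundle = atlas.bundles[edge]
        fname = f"bundle_{edge[0]:04d}_{edge[1]:04d}.nii.gz"
        img = nib.Nifti1Image(atlas.probability_map(edge), atlas.affine)
        nib.save(img, path / fname)
        records.append(
            {
                "node_a": edge[0],
                "node_b": edge[1],
                "presence": bundle.presence,
                "map": fname,
            }
        )
    pd.DataFrame(
        records, columns=["node_a", "node_b", "presence", "map"]
    ).to_csv(path / "edges.tsv", sep="\t", index=False)
    return path


def load_bundle_atlas(path: str | Path) -> BundleAtlas:
    """Load an atlas container directory written by :func:`save_bundle_atlas`.

    All probability maps must share the grid geometry of the first; edges
    referring to unknown nodes are rejected.
    """
    path = Path(path)
    nodes = pd.read_csv(path / "nodes.tsv", sep="\t")
    parcellation = ParcellationScheme(nodes)
    edge_index = pd.read_csv(path / "edges.tsv", sep="\t")

    shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None
    bundles: dict[Edge, Bundle] = {}
    for rec in edge_index.itertuples(index=False):
        a, b = int(rec.node_a), int(rec.node_b)
        if not (0 <= a < parcellation.n_nodes and 0 <= b < parcellation.n_nodes):
            raise AtlasError(
                f"edge ({a}, {b}) references a node outside the "
                f"{parcellation.n_nodes}-node parcellation"
            )
        img = nib.load(path / str(rec.map))
        data = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape = data.shape
            affine = img.affine
        elif data.shape != shape or not np.allclose(img.affine, affine):
            raise AtlasError(f"probability map {rec.map} is on a different grid")
        vox = np.argwhere(data > 0)
        order = np.argsort(np.ravel_multi_index(tuple(vox.T), shape)) if len(vox) else []
        vox = vox[order] if len(vox) else vox.reshape(0, 3)
        bundles[canonical_edge(a, b)] = Bundle(
            voxels=vox,
            occupancy=data[tuple(vox.T)] if len(vox) else np.empty(0),
            presence=float(rec.presence),
        )
    if shape is None:  # zero-edge atlas: fall back to a unit grid
        shape, affine = (1, 1, 1), np.eye(4)
    return BundleAtlas(shape=shape, affine=affine, bundles=bundles, parcellation=parcellation)
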