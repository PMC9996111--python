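"""Per-subject structural connectomes from a scalar map and a bundle atlas.

The connectivity strength of a region pair is the unweighted mean of the
scalar (FA) volume over the bundle's *consistent* voxels — those surviving
the atlas occupancy filter — and only edges surviving the population
presence filter are valid. Voxels are accumulated in sorted linear-index
order so the mean is bitwise reproducible regardless of how the atlas
enumerated them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasError, BundleAtlas, canonical_edge, consistent_edges, consistent_voxels

__all__ = [
    "CohortStack",
    "Connectome",
    "build_connectome",
    "edge_mean_fa",
    "stack_cohort",
]

Edge = tuple[int, int]


@dataclasses.dataclass(frozen=True)
class Connectome:
    """Symmetric node x node matrix of bundle-mean FA with a valid-edge mask.

    Invalid entries (diagonal, filtered edges, empty bundles) hold NaN and
    are False in ``valid``.
    """

    matrix: np.ndarray
    valid: np.ndarray
    subject_id: str
    parcellation: "object"

    def __post_init__(self) -> None:
        m, v = np.asarray(self.matrix, float), np.asarray(self.valid, bool)
        if m.shape != v.shape or m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix and valid mask must be square and congruent")
        if not np.array_equal(v, v.T):
            raise ValueError("valid mask must be symmetric")
        vals = m[v]
        if not np.allclose(m[v], m.T[v], equal_nan=True):
            raise ValueError("connectome matrix must be symmetric on valid edges")
        if np.any(v.diagonal()):
            raise ValueError("diagonal must be invalid")
        if vals.size and (np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1):
            raise ValueError("valid edge values must be finite FA in [0, 1]")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "valid", v)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def edge_value(self, a: int, b: int) -> float:
        a, b = canonical_edge(a, b)
        if not self.valid[a, b]:
            raise KeyError(f"edge ({a}, {b}) is not valid in this connectome")
        return float(self.matrix[a, b])

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix and its valid mask as sibling labelled TSV files."""
        path = Path(path)
        labels = [self.parcellation.label(i) for i in range(self.n_nodes)]
        pd.DataFrame(self.matrix, index=labels, columns=labels).to_csv(path, sep="\t")
        mask_path = path.with_name(path.stem + "_valid" + path.suffix)
        pd.DataFrame(self.valid.astype(int), index=labels, columns=labels).to_csv(
            mask_path, sep="\t"
        )


def edge_mean_fa(
    fa_volume: np.ndarray,
    atlas: BundleAtlas,
    edge: Edge,
    occupancy_threshold: float = 0.9,
) -> float:
    """Unweighted mean FA over the edge's consistent voxels; NaN if none survive."""
    fa_volume = np.asarray(fa_volume, dtype=float)
    if fa_volume.shape != atlas.shape:
        raise AtlasError(
            f"FA volume grid {fa_volume.shape} does not match atlas grid {atlas.shape}"
        )
    vox = consistent_voxels(atlas, edge, occupancy_threshold)
    if len(vox) == 0:
        return float("nan")
    return float(np.mean(fa_volume[tuple(vox.T)]))


def build_connectome(
    fa_volume: np.ndarray,
    atlas: BundleAtlas,
    subject_id: str = "",
    presence_threshold: float = 0.8,
    occupancy_threshold: float = 0.9,
) -> Connectome:
    """Project one FA volume onto the atlas: mean FA per retained bundle.

    Valid edges are those passing the population presence filter whose
    consistent-voxel set is nonempty.
    """
    n = atlas.n_nodes
    matrix = np.full((n, n), np.nan)
    valid = np.zeros((n, n), dtype=bool)
    for edge in sorted(consistent_edges(atlas, presence_threshold)):
        value = edge_mean_fa(fa_volume, atlas, edge, occupancy_threshold)
        if np.isnan(value):
            continue
        a, b = edge
        matrix[a, b] = matrix[b, a] = value
        valid[a, b] = valid[b, a] = True
    return Connectome(matrix=matrix, valid=valid, subject_id=subject_id, parcellation=atlas.parcellation)


@dataclasses.dataclass(frozen=True)
class CohortStack:
    """Cohort of connectomes vectorised for group analysis.

    ``data`` is (n_subjects, n_edges); ``edge_index`` lists the canonical
    node pair behind each column in fixed upper-triangle row-major order.
    Edges enter the stack only if valid in *every* subject.
    """

    data: np.ndarray
    edge_index: list[Edge]
    subject_ids: list[str]
    parcellation: "object"

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]

    def column(self, edge: Edge) -> np.ndarray:
        return self.data[:, self.edge_index.index(canonical_edge(*edge))]

    def unstack(self, subject: int) -> np.ndarray:
        """Rebuild one subject's symmetric matrix (NaN off the shared mask)."""
        n = self.parcellation.n_nodes
        matrix = np.full((n, n), np.nan)
        for value, (a, b) in zip(self.data[subject], self.edge_index):
            matrix[a, b] = matrix[b, a] = value
        return matrix

    def to_container(self, path: str | Path) -> None:
        path = Path(path)
        cols = [f"{a}-{b}" for a, b in self.edge_index]
        pd.DataFrame(self.data, index=self.subject_ids, columns=cols).to_csv(
            path, sep="\t", index_label="subject"
        )


def stack_cohort(connectomes: list[Connectome]) -> CohortStack:
    """Stack per-subject connectomes into a subject x edge matrix.

    The shared valid-edge set is the intersection of per-subject masks;
    columns follow the upper triangle in row-major order.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    first = connectomes[0]
    for c in connectomes[1:]:
        if c.n_nodes != first.n_nodes or not c.parcellation.nodes.equals(
            first.parcellation.nodes
        ):
            raise ValueError("connectomes use different parcellations")
    shared = np.logical_and.reduce([c.valid for c in connectomes])
    rows, cols = np.triu_indices(first.n_nodes, k=1)
    keep = shared[rows, cols]
    edge_index = [(int(a), int(b)) for a, b in zip(rows[keep], cols[keep])]
    data = np.stack([c.matrix[rows[keep], cols[keep]] for c in connectomes])
    return CohortStack(
        data=data,
        edge_index=edge_index,
        subject_ids=[c.subject_id for c in connectomes],
        parcellation=first.parcellation,
    )
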