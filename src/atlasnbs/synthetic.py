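"""Synthetic data with known ground truth for the whole pipeline.

No patient imaging is distributable for this kind of study, so every
input the pipeline needs is generated here with the statistical
structure the analysis assumes:

* a toy parcellation and probabilistic bundle atlas
  (:func:`make_toy_atlas`) whose bundles are voxel-disjoint tubes between
  node seeds, with some edges/voxels deliberately below the consistency
  thresholds;
* per-subject FA phantoms (:func:`simulate_cohort`) in which each
  bundle's FA is linear in a clinical score (planted edges only) plus
  age/sex/acquisition nuisance effects and Gaussian noise, painted
  uniformly over the bundle so the edge-level effect equals the
  configured slope exactly;
* diffusion-weighted signals from known tensors
  (:func:`simulate_dwi_signals`) for testing the tensor fit; and
* motion/outlier QC tables (:func:`simulate_qc_metrics`) with
  self-labelled planted failures.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import Bundle, BundleAtlas, ParcellationScheme, canonical_edge, consistent_edges, consistent_voxels
from .design import ACQUISITION_COLUMNS
from .dti import QC_THRESHOLDS

__all__ = [
    "GroundTruth",
    "SyntheticCohortConfig",
    "default_planted_edges",
    "make_gradient_scheme",
    "make_toy_atlas",
    "simulate_cohort",
    "simulate_dwi_signals",
    "simulate_qc_metrics",
    "write_dataset",
]

Edge = tuple[int, int]

BACKGROUND_FA = 0.15


# ---------------------------------------------------------------------------
# toy atlas


def _node_seats(n_nodes: int, grid_shape: tuple[int, int, int], rng) -> np.ndarray:
    """Deterministic lattice placement of node seed voxels with small jitter."""
    side = int(np.ceil(n_nodes ** (1 / 3)))
    spacing = np.array(grid_shape) // side
    if np.any(spacing < 4):
        raise ValueError(
            f"grid {grid_shape} too small to place {n_nodes} disjoint node seeds"
        )
    seats = []
    for i in range(n_nodes):
        cell = np.array([i % side, (i // side) % side, i // side**2])
        center = (cell + 0.5) * spacing
        jitter = rng.integers(-1, 2, size=3)
        seats.append(np.clip(center + jitter, 1, np.array(grid_shape) - 2).astype(int))
    return np.array(seats)


def _tube_voxels(p0: np.ndarray, p1: np.ndarray, grid_shape) -> np.ndarray:
    """Voxels of a straight 1-voxel-thick tube from p0 to p1 (unique, in-grid)."""
    length = int(np.ceil(np.linalg.norm(p1 - p0))) * 4 + 2
    pts = np.rint(np.linspace(p0, p1, length)).astype(int)
    pts = np.clip(pts, 0, np.array(grid_shape) - 1)
    return np.unique(pts, axis=0)


def make_toy_atlas(
    n_nodes: int = 12,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    extra_edges: int | None = None,
) -> BundleAtlas:
    """Small probabilistic bundle atlas for tests and demonstrations.

    Edges form a ring over the nodes plus ``extra_edges`` random chords
    (default ``n_nodes // 2``). Every fourth edge (in canonical order)
    receives a population presence below 0.8, and roughly a fifth of each
    bundle's voxels an occupancy below 0.9, so both consistency filters
    have something to remove. Bundles are voxel-disjoint by construction:
    a voxel claimed by an earlier bundle is dropped from later ones.
    """
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    rng = np.random.default_rng(seed)
    grid_shape = tuple(int(s) for s in grid_shape)
    seats = _node_seats(n_nodes, grid_shape, rng)

    edges = {canonical_edge(i, (i + 1) % n_nodes) for i in range(n_nodes)}
    n_extra = n_nodes // 2 if extra_edges is None else extra_edges
    while len(edges) < n_nodes + n_extra:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        edges.add(canonical_edge(int(a), int(b)))

    used: set[int] = set()
    bundles: dict[Edge, Bundle] = {}
    for rank, edge in enumerate(sorted(edges)):
        vox = _tube_voxels(seats[edge[0]], seats[edge[1]], grid_shape)
        flat = np.ravel_multi_index(tuple(vox.T), grid_shape)
        keep = np.array([f not in used for f in flat])
        vox, flat = vox[keep], flat[keep]
        if len(vox) < 3:
            continue  # fully shadowed by earlier bundles; drop the edge
        used.update(flat.tolist())
        occupancy = rng.uniform(0.92, 1.0, size=len(vox))
        n_low = max(1, len(vox) // 5) if len(vox) > 4 else 0
        if n_low:
            low_idx = rng.choice(len(vox), size=n_low, replace=False)
            occupancy[low_idx] = rng.uniform(0.5, 0.85, size=n_low)
        presence = (
            float(rng.uniform(0.5, 0.75))
            if rank % 4 == 3
            else float(rng.uniform(0.85, 1.0))
        )
        order = np.argsort(flat)
        bundles[edge] = Bundle(voxels=vox[order], occupancy=occupancy[order], presence=presence)

    nodes = pd.DataFrame(
        {
            "id": np.arange(n_nodes),
            "name": [f"region_{i:02d}" for i in range(n_nodes)],
            "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(n_nodes)],
            "x": seats[:, 0].astype(float),
            "y": seats[:, 1].astype(float),
            "z": seats[:, 2].astype(float),
        }
    )
    return BundleAtlas(
        shape=grid_shape,
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        bundles=bundles,
        parcellation=ParcellationScheme(nodes),
    )


def default_planted_edges(
    atlas: BundleAtlas, k: int = 6, presence_threshold: float = 0.8
) -> list[Edge]:
    """A connected path of ``k`` retained edges, for planting subnetwork effects."""
    graph = nx.Graph(sorted(consistent_edges(atlas, presence_threshold)))
    for source in sorted(graph.nodes):
        for target in sorted(graph.nodes):
            if source < target:
                for path in nx.all_simple_paths(graph, source, target, cutoff=k):
                    if len(path) == k + 1:
                        return [canonical_edge(a, b) for a, b in zip(path, path[1:])]
    raise ValueError(f"atlas has no connected path of {k} retained edges")


# ---------------------------------------------------------------------------
# cohort forward model


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    """Forward-model settings for a synthetic cohort.

    ``effect_slope`` is in FA units per standard deviation of the
    clinical score and is applied to the planted edges only;
    ``nuisance_slopes`` are FA units per (centred) year of age, per sex
    unit, and per unit of the latent acquisition factor, applied to every
    bundle. ``noise_sd`` is i.i.d. Gaussian per voxel; ``edge_noise_sd``
    optionally adds noise shared across a bundle's voxels.
    """

    n_subjects: int = 40
    planted_edges: tuple[Edge, ...] = ()
    # negative by default: higher DRS (worse outcome) goes with lower bundle FA
    effect_slope: float = -0.05
    baseline_fa: float = 0.5
    baseline_jitter: float = 0.05
    noise_sd: float = 0.02
    edge_noise_sd: float = 0.0
    nuisance_slopes: tuple[float, float, float] = (-0.0003, 0.005, 0.003)
    score_name: str = "DRS"
    score_range: tuple[int, int] = (0, 29)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 7:
            raise ValueError("need at least 7 subjects (design columns + 2)")
        if not 0.0 < self.baseline_fa < 1.0:
            raise ValueError("baseline FA must lie strictly inside (0, 1)")
        if self.noise_sd < 0 or self.edge_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        lo, hi = self.score_range
        if hi <= lo:
            raise ValueError("score range must be a nonempty integer interval")
        object.__setattr__(
            self,
            "planted_edges",
            tuple(canonical_edge(a, b) for a, b in self.planted_edges),
        )


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for oracle-style checks."""

    planted_edges: tuple[Edge, ...]
    edge_values: pd.DataFrame  # index: 'a-b' edge keys; columns: subject ids
    edge_baselines: dict[Edge, float]
    score: np.ndarray
    score_z: np.ndarray
    covariates: pd.DataFrame
    latent_acquisition: np.ndarray
    config: SyntheticCohortConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges": [list(e) for e in self.planted_edges],
            "edge_values": {
                k: list(map(float, v)) for k, v in self.edge_values.iterrows()
            },
            "edge_baselines": {f"{a}-{b}": v for (a, b), v in self.edge_baselines.items()},
            "score": self.score.tolist(),
            "latent_acquisition": self.latent_acquisition.tolist(),
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _simulate_records(config: SyntheticCohortConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """Cohort table with the demographic mix of a neurorehabilitation coma cohort."""
    n = config.n_subjects
    age = np.clip(np.rint(rng.normal(53.5, 16.4, size=n)), 16, 84).astype(int)
    sex = np.where(rng.random(n) < 0.4, "f", "m")
    etiology = rng.choice(
        ["CVA", "TBI", "ANOX", "ENC", "LEUCO"], size=n, p=[0.45, 0.375, 0.10, 0.05, 0.025]
    )
    diagnosis = rng.choice(["COMA", "VS/UWS", "MCS"], size=n, p=[0.325, 0.40, 0.275])
    lo, hi = config.score_range
    while True:  # scores must vary for z-scoring; a tie across all subjects is astronomically rare
        score = rng.integers(lo, hi + 1, size=n)
        if np.ptp(score) > 0:
            break
    other = rng.integers(0, 24, size=n)

    # one-factor model with high loadings: the four protocol parameters are
    # strongly inter-dependent (scanner/protocol generation drives them all)
    latent = rng.standard_normal(n)
    loadings = np.array([0.97, 0.95, 0.93, 0.90])
    centers = np.array([6700.0, 78.0, 24.0, 2.45])
    scales = np.array([1100.0, 9.0, 2.5, 0.34])
    unique = rng.standard_normal((n, 4)) * np.sqrt(1 - loadings**2)
    acq = centers + scales * (latent[:, None] * loadings + unique)
    acq[:, 2] = np.clip(np.rint(acq[:, 2]), 18, 30)
    acq[:, 0] = np.clip(acq[:, 0], 3900, 9500)
    acq[:, 1] = np.clip(acq[:, 1], 56, 100)
    acq[:, 3] = np.clip(acq[:, 3], 1.6, 3.3)

    records = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:03d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "interval_injury_mri": np.rint(rng.lognormal(np.log(29.5), 0.7, n)).astype(int),
            "interval_mri_discharge": np.rint(rng.lognormal(np.log(27.0), 0.6, n)).astype(int),
            "etiology": etiology,
            "diagnosis": diagnosis,
            "drs_discharge": score if config.score_name == "DRS" else other.clip(0, 29),
            "crsr_discharge": score if config.score_name != "DRS" else other,
            ACQUISITION_COLUMNS[0]: acq[:, 0],
            ACQUISITION_COLUMNS[1]: acq[:, 1],
            ACQUISITION_COLUMNS[2]: acq[:, 2].astype(int),
            ACQUISITION_COLUMNS[3]: acq[:, 3],
        }
    )
    qc = simulate_qc_metrics(n, 0.0, seed=int(rng.integers(2**31)))
    records = pd.concat([records, qc.drop(columns="planted_fail")], axis=1)
    return records, latent


def simulate_cohort(
    atlas: BundleAtlas, config: SyntheticCohortConfig
) -> tuple[list[np.ndarray], pd.DataFrame, GroundTruth]:
    """Generate per-subject FA volumes, a cohort table, and the ground truth.

    Each bundle of the atlas is painted uniformly with its designed edge
    value — baseline (+ per-edge jitter) + score effect on planted edges
    + nuisance terms — so the bundle mean reproduces the designed value
    exactly at zero noise. Per-voxel Gaussian noise is then added to the
    whole volume and the result clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    retained = {
        e
        for e in consistent_edges(atlas)
        if len(consistent_voxels(atlas, e)) > 0
    }
    for edge in config.planted_edges:
        if edge not in atlas.bundles:
            raise ValueError(f"planted edge {edge} is not in the atlas")
        if edge not in retained:
            raise ValueError(
                f"planted edge {edge} is removed by the consistency filters; "
                "its effect would be unobservable"
            )

    records, latent = _simulate_records(config, rng)
    score = records[
        "drs_discharge" if config.score_name == "DRS" else "crsr_discharge"
    ].to_numpy(dtype=float)
    score_z = (score - score.mean()) / score.std(ddof=1)
    age_c = records["age"].to_numpy(dtype=float) - records["age"].mean()
    sex_c = records["sex"].map({"f": 0.0, "m": 1.0}).to_numpy() - 0.5
    a_age, a_sex, a_acq = config.nuisance_slopes
    nuisance = a_age * age_c + a_sex * sex_c + a_acq * latent

    edges = atlas.edges
    jitter = config.baseline_jitter
    baselines = {e: float(config.baseline_fa + rng.uniform(-jitter, jitter)) for e in edges}

    planted = set(config.planted_edges)
    values = np.empty((len(edges), config.n_subjects))
    for i, edge in enumerate(edges):
        effect = config.effect_slope * score_z if edge in planted else 0.0
        shared = (
            rng.normal(0.0, config.edge_noise_sd, config.n_subjects)
            if config.edge_noise_sd > 0
            else 0.0
        )
        values[i] = baselines[edge] + effect + nuisance + shared

    volumes: list[np.ndarray] = []
    n_clipped = 0
    for s in range(config.n_subjects):
        vol = np.full(atlas.shape, BACKGROUND_FA)
        for i, edge in enumerate(edges):
            bundle = atlas.bundles[edge]
            vol[tuple(bundle.voxels.T)] = values[i, s]
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, atlas.shape)
        n_clipped += int(np.count_nonzero((vol < 0) | (vol > 1)))
        volumes.append(np.clip(vol, 0.0, 1.0))

    truth = GroundTruth(
        planted_edges=config.planted_edges,
        edge_values=pd.DataFrame(
            values, index=[f"{a}-{b}" for a, b in edges], columns=records["subject"]
        ),
        edge_baselines=baselines,
        score=score,
        score_z=score_z,
        covariates=records[["age", "sex"] + ACQUISITION_COLUMNS].copy(),
        latent_acquisition=latent,
        config=config,
    )
    if n_clipped:
        import warnings

        warnings.warn(
            f"{n_clipped} voxel values clipped to [0, 1]; designed effects may be distorted",
            RuntimeWarning,
            stacklevel=2,
        )
    return volumes, records, truth


# ---------------------------------------------------------------------------
# diffusion signals


def make_gradient_scheme(
    n_directions: int = 30, n_b0: int = 1, bval: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic gradient table: b=0 volumes plus a Fibonacci-sphere shell."""
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions")
    i = np.arange(n_directions)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_directions
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    return bvals, bvecs


def simulate_dwi_signals(
    tensor, bvals, bvecs, s0: float = 1.0, noise_sd: float = 0.0, seed: int | None = None
) -> np.ndarray:
    """Single-tensor forward model ``S = S0 exp(-b g'Dg)`` with optional noise."""
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T):
        raise ValueError("tensor must be symmetric 3x3")
    if np.linalg.eigvalsh(D).min() < -1e-12:
        raise ValueError("tensor must be positive semidefinite")
    bvals = np.asarray(bvals, dtype=float).reshape(-1)
    bvecs = np.asarray(bvecs, dtype=float).reshape(-1, 3)
    if len(bvals) != len(bvecs):
        raise ValueError("bvals and bvecs lengths differ")
    if np.any(bvals < 0):
        raise ValueError("negative b-value")
    dw = bvals > 0
    if np.any(np.abs(np.linalg.norm(bvecs[dw], axis=1) - 1.0) > 1e-6):
        raise ValueError("diffusion-weighted bvecs must be unit vectors")
    quad = np.einsum("ij,jk,ik->i", bvecs, D, bvecs)
    signal = s0 * np.exp(-bvals * quad)
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0, noise_sd, len(signal))
    return signal


# ---------------------------------------------------------------------------
# QC metrics


def simulate_qc_metrics(n_subjects: int, fail_fraction: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """QC table (absolute/relative motion in mm, outlier %) with planted failures.

    Approximately ``fail_fraction`` of subjects exceed at least two of the
    exclusion thresholds; the ``planted_fail`` column records which.
    """
    if not 0.0 <= fail_fraction <= 1.0:
        raise ValueError("fail_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fail = int(round(n_subjects * fail_fraction))
    fail = np.zeros(n_subjects, dtype=bool)
    fail[rng.choice(n_subjects, size=n_fail, replace=False)] = True

    abs_m = rng.uniform(0.2, 1.5, n_subjects)
    rel_m = rng.uniform(0.05, 0.4, n_subjects)
    out_p = rng.uniform(0.0, 1.5, n_subjects)
    thr = QC_THRESHOLDS
    for i in np.flatnonzero(fail):
        # exceed 2 or all 3 thresholds
        which = rng.permutation(3)[: rng.integers(2, 4)]
        if 0 in which:
            abs_m[i] = rng.uniform(thr["avg_abs_motion"], 2 * thr["avg_abs_motion"])
        if 1 in which:
            rel_m[i] = rng.uniform(thr["avg_rel_motion"], 2 * thr["avg_rel_motion"])
        if 2 in which:
            out_p[i] = rng.uniform(thr["outlier_pct"], 3 * thr["outlier_pct"])
    return pd.DataFrame(
        {
            "avg_abs_motion": abs_m,
            "avg_rel_motion": rel_m,
            "outlier_pct": out_p,
            "planted_fail": fail,
        }
    )


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(
    out_dir: str | Path,
    atlas: BundleAtlas,
    volumes: list[np.ndarray],
    records: pd.DataFrame,
    truth: GroundTruth,
) -> Path:
    """Write a complete synthetic dataset: atlas container, FA NIfTIs, cohort TSV, truth JSON."""
    from .atlas import save_bundle_atlas

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_bundle_atlas(atlas, out / "atlas")
    fa_dir = out / "fa"
    fa_dir.mkdir(exist_ok=True)
    for vol, subject in zip(volumes, records["subject"]):
        nib.save(nib.Nifti1Image(vol, atlas.affine), fa_dir / f"{subject}_fa.nii.gz")
    records.to_csv(out / "cohort.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
    return out
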