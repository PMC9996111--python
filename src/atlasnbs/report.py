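"""Subnetwork summaries, cohort descriptive statistics, and interchange export.

Covers the reporting side of a clinical connectome study: nodal degrees
of a significant component, the per-subject mean FA across a
subnetwork's edges and its Spearman correlation with a clinical score,
descriptive statistics of a cohort table, and BrainNet Viewer
``.node``/``.edge`` export for visualisation elsewhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CohortStack
from .nbs import Component

__all__ = [
    "SubnetworkSummary",
    "cohort_descriptives",
    "exclusion_summary",
    "export_brainnet",
    "nodal_degrees",
    "spearman_rho",
    "subnetwork_mean_fa",
    "summarize_component",
]

# quantile method reproducing the reporting convention of clinical tables
# (midpoint of the bracketing order statistics)
_IQR_METHOD = "midpoint"


def nodal_degrees(component: Component) -> dict[int, int]:
    """Number of component edges incident to each node."""
    if component.size == 0:
        raise ValueError("component has no edges")
    degrees: dict[int, int] = {n: 0 for n in component.nodes}
    for a, b in component.edges:
        degrees[a] += 1
        degrees[b] += 1
    return degrees


def subnetwork_mean_fa(stack: CohortStack, component: Component) -> np.ndarray:
    """Per-subject unweighted mean FA across the component's edges."""
    missing = [e for e in component.edges if e not in stack.edge_index]
    if missing:
        raise KeyError(f"component edges missing from the stack: {missing}")
    cols = [stack.edge_index.index(e) for e in component.edges]
    return stack.data[:, cols].mean(axis=1)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclasses.dataclass(frozen=True)
class SubnetworkSummary:
    """Report-ready view of one significant subnetwork."""

    nodes: dict[int, int]  # node -> degree
    edges: tuple[tuple[int, int], ...]
    t_values: tuple[float, ...]
    n_nodes: int
    n_edges: int
    p_fwer: float | None
    subject_mean_fa: np.ndarray
    spearman: tuple[float, float] | None

    def to_dict(self, parcellation=None) -> dict:
        label = (lambda n: parcellation.label(n)) if parcellation is not None else str
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "p_fwer": self.p_fwer,
            "degrees": {label(n): d for n, d in sorted(self.nodes.items())},
            "edges": [
                {"node_a": label(a), "node_b": label(b), "t": t}
                for (a, b), t in zip(self.edges, self.t_values)
            ],
            "spearman_rho": None if self.spearman is None else self.spearman[0],
            "spearman_p": None if self.spearman is None else self.spearman[1],
        }


def summarize_component(
    component: Component, stack: CohortStack, scores=None
) -> SubnetworkSummary:
    """Degrees, per-subject subnetwork FA, and (if scores given) Spearman rho."""
    degrees = nodal_degrees(component)
    mean_fa = subnetwork_mean_fa(stack, component)
    spearman = None if scores is None else spearman_rho(mean_fa, scores)
    return SubnetworkSummary(
        nodes=degrees,
        edges=component.edges,
        t_values=component.t_values,
        n_nodes=len(component.nodes),
        n_edges=component.size,
        p_fwer=component.p_fwer,
        subject_mean_fa=mean_fa,
        spearman=spearman,
    )


def _median_iqr_ks(values: np.ndarray) -> dict:
    out = {
        "median": float(np.median(values)),
        "iqr": float(
            np.percentile(values, 75, method=_IQR_METHOD)
            - np.percentile(values, 25, method=_IQR_METHOD)
        ),
    }
    out.update(_ks_normal(values))
    return out


def _ks_normal(values: np.ndarray) -> dict:
    sd = np.std(values, ddof=1)
    if sd == 0:
        return {"ks_d": None, "ks_p": None}
    res = stats.kstest(values, "norm", args=(np.mean(values), sd))
    return {"ks_d": float(res.statistic), "ks_p": float(res.pvalue)}


def cohort_descriptives(records: pd.DataFrame) -> dict:
    """Descriptive statistics of a cohort table.

    Age: mean and SD (n-1 denominator) plus a one-sample Kolmogorov-
    Smirnov test against a normal with the sample mean/SD. Scores and
    intervals: median, IQR (midpoint quantiles) and the same KS test.
    Diagnosis tallies count transitional "MCS-" rows as MCS.
    """
    if len(records) == 0:
        raise ValueError("empty cohort table")
    n = len(records)
    age = records["age"].to_numpy(dtype=float)
    out: dict = {"n": n, "n_female": int((records["sex"] == "f").sum())}
    age_stats = {
        "mean": float(age.mean()),
        "sd": float(np.std(age, ddof=1)) if n > 1 else None,
        "min": float(age.min()),
        "max": float(age.max()),
    }
    age_stats.update(_ks_normal(age) if n > 1 else {"ks_d": None, "ks_p": None})
    out["age"] = age_stats
    for key, col in [
        ("drs_discharge", "drs_discharge"),
        ("crsr_discharge", "crsr_discharge"),
        ("interval_injury_mri", "interval_injury_mri"),
        ("interval_mri_discharge", "interval_mri_discharge"),
    ]:
        if col in records.columns:
            out[key] = _median_iqr_ks(records[col].to_numpy(dtype=float))
    out["etiology"] = records["etiology"].value_counts().to_dict()
    diagnosis = records["diagnosis"].replace({"MCS-": "MCS"})
    out["diagnosis"] = diagnosis.value_counts().to_dict()
    return out


def exclusion_summary(records: pd.DataFrame, stage_exclusions: dict[str, int]) -> dict:
    """Screening funnel: stage-wise exclusion counts and the analysed n.

    The analysed sample size is the cohort table's row count — the ground
    truth of who entered the analysis — reported alongside the stated
    stage counts rather than derived from them.
    """
    return {
        "excluded": dict(stage_exclusions),
        "total_excluded": int(sum(stage_exclusions.values())),
        "final_n": len(records),
    }


def export_brainnet(component: Component, parcellation, path: str | Path) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files for a component.

    ``.node``: one row per component node — x, y, z (mm), color code
    (constant 1), size = nodal degree, label (spaces replaced by dots).
    ``.edge``: symmetric n_nodes x n_nodes matrix of t-values over the
    component's node list (node-file order), zero elsewhere.
    """
    path = Path(path)
    degrees = nodal_degrees(component)
    order = sorted(component.nodes)
    rows = []
    for node in order:
        xyz = parcellation.coordinates(node)
        if np.any(~np.isfinite(xyz)):
            raise ValueError(f"node {node} has no coordinates")
        label = parcellation.label(node).replace(" ", ".")
        rows.append(f"{xyz[0]:.3f}\t{xyz[1]:.3f}\t{xyz[2]:.3f}\t1\t{degrees[node]}\t{label}")
    node_path = path.with_suffix(".node")
    node_path.write_text("\n".join(rows) + "\n")

    index = {node: i for i, node in enumerate(order)}
    mat = np.zeros((len(order), len(order)))
    for (a, b), t in zip(component.edges, component.t_values):
        mat[index[a], index[b]] = mat[index[b], index[a]] = t
    edge_path = path.with_suffix(".edge")
    np.savetxt(edge_path, mat, fmt="%.6g", delimiter="\t")
    return node_path, edge_path
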