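"""Packaged study tables: a 40-patient coma-recovery cohort and its subnetworks.

The package ships, as plain TSV, the published demographic/clinical table
of a 40-patient cohort in pathological recovery after coma (sex, age,
injury-to-MRI and MRI-to-discharge intervals, etiology, diagnosis at
admission, DRS and CRS-R at discharge), and the edge lists — with their
GLM t-values — of the two structural subnetworks whose mean FA was found
to track the discharge scores (one per score, at primary threshold
t = 3.5). These are inputs for the reporting and graph-summary side of
the pipeline; the underlying patient imaging is not distributable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .nbs import Component

__all__ = [
    "EXCLUSION_STAGES",
    "load_cohort_table",
    "load_reported_subnetwork",
    "reported_component",
]

# screening funnel of the cohort: scans available, then stage-wise exclusions
SCREENED_N = 148
AVAILABLE_DWI_N = 52
EXCLUSION_STAGES = {
    "susceptibility_artefacts": 7,
    "interslice_inconsistencies": 2,
    "motion_qc": 4,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("atlasnbs.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_cohort_table() -> pd.DataFrame:
    """The 40-row cohort table (one row per analysed patient)."""
    table = _read("coma_cohort.tsv")
    table["subject"] = table["subject"].astype(str)
    return table


def load_reported_subnetwork(score: str) -> pd.DataFrame:
    """Edge list (region_a, region_b, t) of the score-associated subnetwork.

    ``score`` is ``"DRS"`` (29 nodes / 41 edges) or ``"CRS-R"``
    (8 nodes / 8 edges).
    """
    key = score.upper().replace("-", "")
    if key == "DRS":
        return _read("subnetwork_edges_drs.tsv")
    if key == "CRSR":
        return _read("subnetwork_edges_crsr.tsv")
    raise ValueError(f"unknown score {score!r}; expected 'DRS' or 'CRS-R'")


def reported_component(score: str) -> tuple[Component, dict[int, str]]:
    """The reported subnetwork as a :class:`Component` plus an id -> region-name map.

    Region names are assigned integer ids in sorted order, so degrees and
    graph summaries computed on the component can be mapped back to
    anatomical labels.
    """
    edges_df = load_reported_subnetwork(score)
    names = sorted(set(edges_df["region_a"]) | set(edges_df["region_b"]))
    idx = {name: i for i, name in enumerate(names)}
    edges, tvals = [], []
    for rec in edges_df.itertuples(index=False):
        a, b = idx[rec.region_a], idx[rec.region_b]
        edges.append((min(a, b), max(a, b)))
        tvals.append(float(rec.t))
    component = Component(
        nodes=frozenset(idx.values()), edges=tuple(edges), t_values=tuple(tvals)
    )
    return component, {i: name for name, i in idx.items()}
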