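"""Regression design for edge-wise clinical-score association.

The model tested at every connectome edge is

    FA_edge = b0 + b1 * score + b2 * age + b3 * sex + b4 * acq_pc1 + eps

where ``score`` is a discharge outcome scale (DRS, 0 = no disability to
29 = extreme vegetative state; or CRS-R, 0-23 with higher = more
conscious) and ``acq_pc1`` compresses four collinear acquisition
parameters (TR, TE, number of diffusion directions, interslice gap) into
the first principal component of their correlation structure. The tested
contrast is the unit vector on the score column; for DRS the contrast is
negated, because a *better* outcome is a *lower* DRS, so the hypothesised
FA association is negative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "ACQUISITION_COLUMNS",
    "DesignMatrix",
    "acquisition_pc1",
    "build_design",
    "validate_records",
]

ACQUISITION_COLUMNS = ["tr_ms", "te_ms", "n_directions", "gap_mm"]

SCORE_COLUMN = {"DRS": "drs_discharge", "CRS-R": "crsr_discharge", "CRSR": "crsr_discharge"}
SCORE_RANGE = {"drs_discharge": (0, 29), "crsr_discharge": (0, 23)}
DEFAULT_DIRECTION = {"DRS": "negative", "CRS-R": "positive", "CRSR": "positive"}

REQUIRED_COLUMNS = [
    "subject",
    "sex",
    "age",
    "etiology",
    "diagnosis",
    "drs_discharge",
    "crsr_discharge",
]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a subject table against the record invariants and return it."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"subject table missing columns {missing}")
    if (records["age"] <= 0).any():
        raise ValueError("ages must be positive")
    for col, (lo, hi) in SCORE_RANGE.items():
        v = records[col]
        if (v < lo).any() or (v > hi).any():
            raise ValueError(f"{col} outside [{lo}, {hi}]")
    if not records["sex"].isin(["f", "m"]).all():
        raise ValueError("sex must be coded 'f' or 'm'")
    return records


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """Subject x predictor matrix with named columns and a contrast vector."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ValueError("design shape does not match column names")
        if c.shape != (X.shape[1],) or not np.any(c):
            raise ValueError("contrast must be a nonzero vector over the columns")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(_rank_deficiency_message(X, self.columns))
        if X.shape[0] <= rank:
            raise ValueError("need more subjects than design columns")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "contrast", c)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.rank

    def reduced(self) -> np.ndarray:
        """Design with the contrasted column(s) removed (nuisance-only model)."""
        keep = self.contrast == 0
        return self.X[:, keep]


def _rank_deficiency_message(X: np.ndarray, columns: list[str]) -> str:
    offending = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
            offending.append(columns[j])
    return f"design is rank deficient; linearly dependent columns: {offending or columns}"


def acquisition_pc1(params: pd.DataFrame) -> np.ndarray:
    """First-principal-component scores of the (z-scored) acquisition parameters.

    The four parameters carry incommensurate units, so each column is
    z-scored before the PCA (correlation PCA). The component's sign is
    fixed so that the loading of the first column is nonnegative; any
    fixed convention leaves downstream regression inference unchanged.
    """
    M = np.asarray(params, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a subject x parameter table with >= 2 subjects")
    if np.isnan(M).any():
        raise ValueError("missing values in acquisition parameters")
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = list(params.columns) if hasattr(params, "columns") else list(range(M.shape[1]))
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant acquisition column(s) {bad}: cannot z-score")
    Z = (M - M.mean(axis=0)) / sd
    # principal axes of the correlation structure via SVD of the z-scores
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    if Vt[0, 0] < 0:
        scores = -scores
    return scores


def explained_variance_ratio(params: pd.DataFrame) -> np.ndarray:
    """Share of correlation-structure variance carried by each component."""
    M = np.asarray(params, dtype=float)
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    s = np.linalg.svd(Z, compute_uv=False) ** 2
    return s / s.sum()


def build_design(
    records: pd.DataFrame,
    score_name: str = "DRS",
    direction: str | None = None,
) -> DesignMatrix:
    """Assemble [intercept, score, age, sex, acq_pc1] with the score contrast.

    ``direction`` defaults to the hypothesised direction of the FA
    association: negative for DRS (lower score = better outcome), positive
    for CRS-R.
    """
    if score_name not in SCORE_COLUMN:
        raise ValueError(f"unknown score {score_name!r}; expected DRS or CRS-R")
    direction = direction or DEFAULT_DIRECTION[score_name]
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    validate_records(records)
    missing = [c for c in ACQUISITION_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack acquisition columns {missing}")
    if records[ACQUISITION_COLUMNS + ["age", "sex"]].isna().any().any():
        raise ValueError("missing covariate values; records must be complete")

    if len(records) < 7:  # 5 columns + 2 residual df
        raise ValueError("need at least 7 complete records to fit the 5-column design")

    score = records[SCORE_COLUMN[score_name]].to_numpy(dtype=float)
    sex = records["sex"].map({"f": 0.0, "m": 1.0}).to_numpy()
    pc1 = acquisition_pc1(records[ACQUISITION_COLUMNS])
    X = np.column_stack(
        [np.ones(len(records)), score, records["age"].to_numpy(dtype=float), sex, pc1]
    )
    contrast = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    if direction == "negative":
        contrast = -contrast
    return DesignMatrix(
        X=X,
        columns=["intercept", "score", "age", "sex", "acq_pc1"],
        contrast=contrast,
        subject_ids=[str(s) for s in records["subject"]],
    )
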