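"""Diffusion-tensor essentials: OLS tensor fit, fractional anisotropy, QC screen.

The diffusion signal under the single-tensor model is
``S(b, g) = S0 * exp(-b * g' D g)`` with ``D`` a symmetric positive
semidefinite 3x3 tensor (mm^2/s) and ``g`` a unit gradient direction.
Taking logs makes the model linear in ``(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz,
Dyz)``, which is fit here by ordinary least squares on the log-signal.

Fractional anisotropy (FA) summarises the tensor's eigenvalues
``l1 >= l2 >= l3 >= 0``::

    FA = sqrt(1/2) * sqrt(((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2)
                          / (l1^2 + l2^2 + l3^2))

FA is 0 for isotropic diffusion, 1 in the limit of a single nonzero
eigenvalue, and scale-invariant.

The QC screen applies the motion/outlier exclusion rule used for
diffusion acquisitions in uncooperative patients: a scan is excluded when
at least two of {average absolute motion >= 2 mm, average relative motion
>= 0.5 mm, outlier slice percentage >= 2%} hold (inclusive comparisons).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

__all__ = [
    "QCMetrics",
    "QC_THRESHOLDS",
    "TensorFit",
    "fa_volume",
    "fit_tensor_ols",
    "fractional_anisotropy",
    "qc_screen",
    "qc_screen_table",
]

logger = logging.getLogger(__name__)

# exclusion thresholds: avg absolute motion (mm), avg relative motion (mm),
# outlier percentage (%)
QC_THRESHOLDS: dict[str, float] = {
    "avg_abs_motion": 2.0,
    "avg_rel_motion": 0.5,
    "outlier_pct": 2.0,
}


@dataclasses.dataclass(frozen=True)
class QCMetrics:
    """Automated diffusion QC metrics for one acquisition."""

    avg_abs_motion: float
    avg_rel_motion: float
    outlier_pct: float

    def __post_init__(self) -> None:
        for name in QC_THRESHOLDS:
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ValueError(f"QC metric {name!r} is missing or non-finite")
            if value < 0:
                raise ValueError(f"QC metric {name!r} must be nonnegative, got {value}")


@dataclasses.dataclass(frozen=True)
class TensorFit:
    """Result of a single-voxel tensor fit.

    ``tensor`` is the symmetric 3x3 diffusion tensor (mm^2/s);
    ``eigenvalues`` are sorted descending and may be slightly negative for
    noisy fits — they are clamped to zero only when computing FA.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    s0: float

    @property
    def fa(self) -> float:
        return float(fractional_anisotropy(np.clip(self.eigenvalues, 0.0, None)))


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx**2,
            -bvals * gy**2,
            -bvals * gz**2,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
        ]
    )


def _check_gradients(bvals: np.ndarray, bvecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.asarray(bvals, dtype=float).reshape(-1)
    bvecs = np.asarray(bvecs, dtype=float).reshape(-1, 3)
    if len(bvals) != len(bvecs):
        raise ValueError("bvals and bvecs lengths differ")
    if np.any(bvals < 0):
        raise ValueError("negative b-value in gradient table")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("diffusion-weighted gradient directions must be unit vectors")
    return bvals, bvecs


def _coefficients_to_tensor(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_tensor_ols(signals, bvals, bvecs) -> TensorFit:
    """Fit the diffusion tensor to one voxel's signals by log-linear OLS.

    Requires at least 7 measurements spanning 6 independent directions plus
    a b=0 acquisition, and strictly positive signals (no silent clamping).
    """
    signals = np.asarray(signals, dtype=float).reshape(-1)
    bvals, bvecs = _check_gradients(bvals, bvecs)
    if len(signals) != len(bvals):
        raise ValueError("signal vector and gradient table lengths differ")
    if np.any(signals <= 0):
        raise ValueError("non-positive signal: cannot take log (check mask/noise floor)")
    if not np.any(bvals == 0):
        raise ValueError("at least one b=0 measurement is required")
    X = _design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient gradient scheme: need >= 6 independent "
            "diffusion directions plus b=0"
        )
    coef, *_ = np.linalg.lstsq(X, np.log(signals), rcond=None)
    tensor = _coefficients_to_tensor(coef[1:])
    eigenvalues = np.linalg.eigvalsh(tensor)[::-1]
    return TensorFit(tensor=tensor, eigenvalues=eigenvalues, s0=float(np.exp(coef[0])))


def fractional_anisotropy(eigenvalues) -> np.ndarray | float:
    """FA from eigenvalue triples (last axis of length 3); all-zero triples give 0.

    Negative eigenvalues are rejected — clamp upstream (as :class:`TensorFit`
    and :func:`fa_volume` do) so that the decision to clamp stays explicit.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples on the last axis")
    if np.any(ev < 0):
        raise ValueError("negative eigenvalue: clamp to zero before computing FA")
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    fa = np.clip(fa, 0.0, 1.0)
    return fa if fa.ndim else float(fa)


def fa_volume(dwi, bvals, bvecs, mask) -> np.ndarray:
    """Voxel-wise FA map from a 4-D diffusion-weighted image.

    Fits the tensor at every masked voxel (vectorised log-linear OLS shared
    across voxels), clamps negative eigenvalues to zero (count logged), and
    returns FA with zeros outside the mask.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4:
        raise ValueError("dwi must be a 4-D array (x, y, z, gradient)")
    if mask.shape != dwi.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    bvals, bvecs = _check_gradients(bvals, bvecs)
    if dwi.shape[3] != len(bvals):
        raise ValueError(
            f"image has {dwi.shape[3]} volumes but gradient table has {len(bvals)}"
        )
    X = _design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient gradient scheme")

    fa = np.zeros(dwi.shape[:3], dtype=float)
    voxels = dwi[mask]  # (n_voxels, n_gradients)
    if voxels.size == 0:
        return fa
    if np.any(voxels <= 0):
        raise ValueError("non-positive signal inside mask")
    coef = np.linalg.lstsq(X, np.log(voxels).T, rcond=None)[0].T  # (n_voxels, 7)
    tensors = np.empty((len(coef), 3, 3))
    c = coef[:, 1:]
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = c[:, 0], c[:, 1], c[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = c[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = c[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = c[:, 5]
    ev = np.linalg.eigvalsh(tensors)[:, ::-1]
    n_clamped = int(np.count_nonzero(np.any(ev < 0, axis=1)))
    if n_clamped:
        logger.info("clamped negative eigenvalues in %d of %d voxels", n_clamped, len(ev))
    fa[mask] = fractional_anisotropy(np.clip(ev, 0.0, None))
    return fa


def qc_screen(metrics: QCMetrics) -> bool:
    """Return True to keep the scan, False to exclude it.

    Exclusion requires at least two of the three metrics at or above their
    thresholds; a single flagged metric keeps the scan. Worsening any metric
    can therefore never rescue an excluded scan.
    """
    n_flagged = sum(
        getattr(metrics, name) >= threshold for name, threshold in QC_THRESHOLDS.items()
    )
    return n_flagged < 2


def qc_screen_table(table) -> np.ndarray:
    """Vectorised :func:`qc_screen` over a DataFrame with the three metric columns."""
    keep = np.ones(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples(index=False)):
        keep[i] = qc_screen(
            QCMetrics(
                avg_abs_motion=float(row.avg_abs_motion),
                avg_rel_motion=float(row.avg_rel_motion),
                outlier_pct=float(row.outlier_pct),
            )
        )
    return keep
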