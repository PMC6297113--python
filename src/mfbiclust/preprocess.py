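"""Normalization and transforms that prepare spectra for factorization.

Raw NMR/MS intensity matrices differ in overall dilution per sample and span
orders of magnitude per variable.  The standard cleanup here is: scale each
sample (total-intensity or median-fold-change normalization), express each
cell as the log fold change against the median spectrum, and finally shift
the matrix so it is entrywise nonnegative as the factorization requires.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

from .datatypes import DataMatrix

__all__ = [
    "median_fold_change_log",
    "median_fold_change_normalize",
    "total_intensity_normalize",
    "shift_to_nonnegative",
    "ShiftResult",
]


def _median_spectrum(values: np.ndarray) -> np.ndarray:
    # per-variable median over samples: the "median spectrum" of the cohort
    return np.median(values, axis=0)


def median_fold_change_log(matrix: DataMatrix, eps: float | None = None) -> DataMatrix:
    """Log fold change of every cell against the per-column median spectrum.

    Each entry becomes ``log(max(x, eps) / max(median_j, eps))`` where
    ``median_j`` is the median of column ``j`` over samples.  ``eps`` floors
    both numerator and denominator so zeros stay finite; it defaults to
    ``1e-12 * max(matrix)``.  An all-zero column maps to zeros (the floored
    ratio is 1) and triggers a warning.
    """
    values = matrix.values
    if np.any(values < 0):
        raise ValueError("median_fold_change_log expects a nonnegative matrix")
    if eps is None:
        top = float(values.max())
        eps = 1e-12 * top if top > 0 else 1e-12
    if eps <= 0:
        raise ValueError("eps must be positive")
    med = _median_spectrum(values)
    zero_cols = np.flatnonzero(med <= 0)
    if zero_cols.size:
        warnings.warn(
            f"{zero_cols.size} column(s) have zero median; their log fold "
            "changes are floored",
            stacklevel=2,
        )
    out = np.log(np.maximum(values, eps) / np.maximum(med, eps)[None, :])
    return matrix.with_values(out)


def total_intensity_normalize(matrix: DataMatrix) -> DataMatrix:
    """Scale every sample (row) to unit total intensity."""
    values = matrix.values
    if np.any(values < 0):
        raise ValueError("total_intensity_normalize expects a nonnegative matrix")
    sums = values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        labels = [matrix.row_labels[i] for i in bad[:5]]
        raise ValueError(f"cannot normalize all-zero row(s): {labels}")
    return matrix.with_values(values / sums[:, None])


def median_fold_change_normalize(matrix: DataMatrix) -> DataMatrix:
    """Divide each sample by the median of its fold changes vs the median spectrum.

    The classic dilution correction for biofluid spectra: the per-sample
    scaling factor is the median, over variables with positive median
    intensity, of ``x_ij / median_j``.
    """
    values = matrix.values
    if np.any(values < 0):
        raise ValueError("median_fold_change_normalize expects a nonnegative matrix")
    med = _median_spectrum(values)
    usable = med > 0
    if not usable.any():
        raise ValueError("median spectrum is identically zero")
    fold = values[:, usable] / med[usable][None, :]
    factors = np.median(fold, axis=1)
    bad = np.flatnonzero(factors <= 0)
    if bad.size:
        labels = [matrix.row_labels[i] for i in bad[:5]]
        raise ValueError(f"non-positive dilution factor for row(s): {labels}")
    return matrix.with_values(values / factors[:, None])


class ShiftResult(NamedTuple):
    """A shifted matrix plus the shift that was applied (0 if none)."""

    matrix: DataMatrix
    shift: float


def shift_to_nonnegative(matrix: DataMatrix) -> ShiftResult:
    """Add a constant so the minimum entry is 0; no-op if already nonnegative.

    Log fold changes are signed while the factorization demands a positive
    matrix, so the pipeline shifts as its final preprocessing step and keeps
    the shift on record for reporting.
    """
    lo = float(matrix.values.min())
    if lo >= 0:
        return ShiftResult(matrix, 0.0)
    return ShiftResult(matrix.with_values(matrix.values - lo), -lo)
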