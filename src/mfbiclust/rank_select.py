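"""Bi-cross-validation (BCV) selection of the number of factors.

Ordinary cross-validation does not apply to an unsupervised factorization:
every cell of the matrix participates in the fit.  BCV instead holds out a
row block ``I`` and a column block ``J`` jointly.  The model is fitted at
rank ``k`` on the retained submatrix ``A[-I, -J]``, and the held-out block is
predicted through the fitted low-rank map:

    Ahat[I, J] = A[I, -J] @ pinv(W H) @ A[-I, J]

where ``W H`` is the rank-k fit of ``A[-I, -J]``.  The squared Frobenius
residual ``||A[I, J] - Ahat[I, J]||_F^2`` is accumulated over a set of
holdout blocks; the rank minimizing the accumulated residual is selected
(smallest rank on ties).  On an exactly rank-r matrix the reconstruction at
``k = r`` is algebraically exact, and on noisy data overfitted ranks inflate
the held-out residual, which is what makes the argmin informative.

The default plan is a seeded 2 x 2 grid: rows and columns are each randomly
partitioned into two folds and all four block combinations are held out, so
every cell is held out exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DataMatrix
from .factorize import nmf_fit

__all__ = [
    "HoldoutPlan",
    "BCVResult",
    "make_holdout_plan",
    "bcv_block_error",
    "select_rank",
]


@dataclass
class HoldoutPlan:
    """List of (row index set, column index set) holdout blocks."""

    holdouts: list[tuple[np.ndarray, np.ndarray]]
    scheme: str

    @property
    def L(self) -> int:
        return len(self.holdouts)


def _as_array(A) -> np.ndarray:
    return A.values if isinstance(A, DataMatrix) else np.asarray(A, dtype=float)


def make_holdout_plan(
    m: int,
    n: int,
    scheme: str = "grid",
    grid_shape: tuple[int, int] = (2, 2),
    n_holdouts: int = 4,
    block_frac: float = 0.3,
    seed: int = 0,
) -> HoldoutPlan:
    """Build the holdout blocks for BCV.

    ``grid`` partitions rows into ``h`` and columns into ``w`` random folds
    (``grid_shape = (h, w)``) and holds out every fold pair, covering each
    cell exactly once (L = h*w).  ``random`` draws ``n_holdouts`` independent
    blocks of ``block_frac`` of each dimension.
    """
    rng = np.random.default_rng(seed)
    if scheme == "grid":
        h, w = grid_shape
        if h < 2 or w < 2 or h > m or w > n:
            raise ValueError(f"grid shape {grid_shape} degenerate for a {m}x{n} matrix")
        row_folds = np.array_split(rng.permutation(m), h)
        col_folds = np.array_split(rng.permutation(n), w)
        holdouts = [
            (np.sort(I), np.sort(J)) for I in row_folds for J in col_folds
        ]
    elif scheme == "random":
        bi = int(round(block_frac * m))
        bj = int(round(block_frac * n))
        if not (1 <= bi < m and 1 <= bj < n):
            raise ValueError(f"block_frac={block_frac} degenerate for a {m}x{n} matrix")
        holdouts = [
            (
                np.sort(rng.choice(m, size=bi, replace=False)),
                np.sort(rng.choice(n, size=bj, replace=False)),
            )
            for _ in range(n_holdouts)
        ]
    else:
        raise ValueError(f"unknown holdout scheme {scheme!r}")
    return HoldoutPlan(holdouts=holdouts, scheme=scheme)


def bcv_block_error(
    A: DataMatrix | np.ndarray,
    k: int,
    I: np.ndarray,
    J: np.ndarray,
    seed: int = 0,
    restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Squared held-out residual of one BCV block at rank ``k``.

    Fits NMF on the retained submatrix and reconstructs the held-out block
    through the pseudo-inverse of the fitted low-rank matrix (SVD-based,
    relative cutoff 1e-10).
    """
    values = _as_array(A)
    m, n = values.shape
    I = np.asarray(I, dtype=int)
    J = np.asarray(J, dtype=int)
    keep_r = np.setdiff1d(np.arange(m), I)
    keep_c = np.setdiff1d(np.arange(n), J)
    if I.size == 0 or J.size == 0 or keep_r.size == 0 or keep_c.size == 0:
        raise ValueError("holdout block and its complement must both be non-empty")
    if k > min(keep_r.size, keep_c.size):
        raise ValueError(
            f"rank k={k} exceeds the retained submatrix size "
            f"{keep_r.size}x{keep_c.size}"
        )
    fit = nmf_fit(
        values[np.ix_(keep_r, keep_c)],
        k,
        seed=seed,
        restarts=restarts,
        tol=tol,
        max_iter=max_iter,
    )
    low_rank = fit.W @ fit.H
    pinv = np.linalg.pinv(low_rank, rcond=1e-10)
    ahat = values[np.ix_(I, keep_c)] @ pinv @ values[np.ix_(keep_r, J)]
    return float(np.linalg.norm(values[np.ix_(I, J)] - ahat, "fro") ** 2)


@dataclass
class BCVResult:
    """Accumulated BCV residual per candidate rank and the selected rank."""

    candidate_ranks: list[int]
    bcv_error: np.ndarray
    selected_k: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.candidate_ranks, "bcv_error": self.bcv_error}
        )


def select_rank(
    A: DataMatrix | np.ndarray,
    candidate_ranks: list[int] | None = None,
    plan: HoldoutPlan | None = None,
    seed: int = 0,
    restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    tie_tol: float = 1e-4,
) -> BCVResult:
    """Accumulate BCV residuals over the plan and pick the minimizing rank.

    Candidates default to ``1..min(10, min(m, n) - 1)`` capped by what the
    retained submatrices can fit.  Ties go to the smallest rank, where
    "tied" means within ``tie_tol`` of the minimum on the scale of the total
    held-out mass (sum of squared Frobenius norms of the held-out blocks):
    on exactly low-rank data every rank at or above the true one leaves a
    residual at the numerical floor, and an extra factor that improves the
    held-out error by less than this fraction of the data's energy does not
    earn its place.
    """
    values = _as_array(A)
    m, n = values.shape
    if plan is None:
        plan = make_holdout_plan(m, n, scheme="grid", seed=seed)
    max_fit = min(
        min(m - I.size, n - J.size) for I, J in plan.holdouts
    )
    if candidate_ranks is None:
        candidate_ranks = list(range(1, min(10, min(m, n) - 1, max_fit) + 1))
    candidate_ranks = sorted(int(k) for k in candidate_ranks)
    if not candidate_ranks:
        raise ValueError("no candidate ranks")
    if candidate_ranks[0] < 1 or candidate_ranks[-1] > max_fit:
        raise ValueError(
            f"candidate ranks must lie in [1, {max_fit}] for this plan"
        )
    errors = np.zeros(len(candidate_ranks))
    held_out_mass = 0.0
    # every holdout uses the same base seed, so the accumulated errors do
    # not depend on the order the blocks are visited in
    for I, J in plan.holdouts:
        held_out_mass += float(np.linalg.norm(values[np.ix_(I, J)], "fro") ** 2)
        for idx, k in enumerate(candidate_ranks):
            errors[idx] += bcv_block_error(
                values,
                k,
                I,
                J,
                seed=seed,
                restarts=restarts,
                tol=tol,
                max_iter=max_iter,
            )
    threshold = errors.min() + tie_tol * held_out_mass
    selected = candidate_ranks[int(np.argmax(errors <= threshold))]
    return BCVResult(
        candidate_ranks=candidate_ranks, bcv_error=errors, selected_k=selected
    )
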