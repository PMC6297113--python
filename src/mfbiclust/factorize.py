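"""Low-rank factorization: nonnegative (NMF) and PCA baselines.

NMF approximates a nonnegative matrix ``A (m x n)`` as ``W H`` with
``W (m x k) >= 0`` and ``H (k x n) >= 0`` by minimizing the Frobenius
objective ``f(W, H) = 1/2 ||A - W H||_F^2`` with Lee–Seung multiplicative
updates, which decrease the objective monotonically.  Columns of ``W`` are
per-factor sample scores, rows of ``H`` per-factor variable loadings; their
nonnegativity is what makes each factor readable as a bicluster candidate.

The PCA baseline returns the rank-k truncated SVD of the matrix itself
(scores ``U_k S_k``, loadings ``V_k^T``), the Frobenius-optimal
unconstrained rank-k approximation; its factors are signed.  The matrix is
deliberately not mean-centered: the spectra are nonnegative and nearly
block-structured, so the uncentered singular vectors stay supported on the
blocks, whereas centering couples every block through the subtracted mean
and destroys the factor-per-bicluster correspondence the baseline is meant
to provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DataMatrix

__all__ = ["FactorizationResult", "nmf_fit", "pca_fit", "reconstruct"]

_DENOM_EPS = 1e-12  # stabilizer added to multiplicative-update denominators


@dataclass
class FactorizationResult:
    """Fitted factors plus the optimization trace.

    ``objective_trace[t]`` is ``1/2 ||A - W H||_F^2`` after iteration ``t``
    of the best restart (a single value for PCA, which is closed-form).
    ``col_mean`` holds the column means removed before the SVD for
    ``method='pca'`` and is ``None`` for NMF.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: np.ndarray
    method: str
    seed: int | None
    restarts: int
    converged: bool
    row_labels: list[str]
    col_labels: list[str]
    col_mean: np.ndarray | None = None

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _as_values(A) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(A, DataMatrix):
        return A.values, list(A.row_labels), list(A.col_labels)
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    return A, [f"S{i + 1}" for i in range(m)], [f"V{j + 1}" for j in range(n)]


def _objective(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(A - W @ H, "fro") ** 2)


def _nmf_single(
    A: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    m, n = A.shape
    mean = A.mean()
    scale = np.sqrt(mean / k) if mean > 0 else 1.0
    W = rng.uniform(0.0, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale
    trace = [_objective(A, W, H)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _DENOM_EPS)
        W *= (A @ H.T) / (W @ (H @ H.T) + _DENOM_EPS)
        obj = _objective(A, W, H)
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= tol * max(prev, np.finfo(float).tiny):
            converged = True
            break
    return W, H, np.asarray(trace), converged


def nmf_fit(
    A: DataMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    restarts: int = 10,
) -> FactorizationResult:
    """Fit rank-``k`` NMF by multiplicative updates, best of seeded restarts.

    Parameters
    ----------
    A
        Nonnegative matrix (DataMatrix or array).
    k
        Rank, ``1 <= k <= min(m, n)``.
    seed
        Base seed; restart ``r`` uses the independent stream ``(seed, r)``.
    tol
        Stop when the relative objective decrease falls below this.
    max_iter
        Iteration cap per restart.
    restarts
        Number of random initializations; the lowest final objective wins.
    """
    values, row_labels, col_labels = _as_values(A)
    if np.any(values < 0):
        raise ValueError(
            "NMF requires a nonnegative matrix; apply shift_to_nonnegative first"
        )
    m, n = values.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank k={k} outside [1, {min(m, n)}]")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        W, H, trace, converged = _nmf_single(values, k, rng, tol, max_iter)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, converged)
    W, H, trace, converged = best
    return FactorizationResult(
        W=W,
        H=H,
        k=k,
        objective_trace=trace,
        method="nmf",
        seed=seed,
        restarts=restarts,
        converged=converged,
        row_labels=row_labels,
        col_labels=col_labels,
    )


def pca_fit(A: DataMatrix | np.ndarray, k: int) -> FactorizationResult:
    """Rank-``k`` truncated singular decomposition of the (uncentered) matrix.

    Scores ``W = U_k S_k`` and loadings ``H = V_k^T``; by Eckart-Young,
    ``W H`` is the best rank-k approximation in Frobenius norm, so its
    residual is never above the NMF residual at the same rank.  Each loading
    row's largest-magnitude entry is flipped positive so the (arbitrary)
    factor signs are reproducible and the dominant side of every factor is
    the positive one.
    """
    values, row_labels, col_labels = _as_values(A)
    m, n = values.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank k={k} outside [1, {min(m, n)}]")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    W = U[:, :k] * s[:k]
    H = Vt[:k].copy()
    for a in range(k):
        j = int(np.argmax(np.abs(H[a])))
        if H[a, j] < 0:
            H[a] = -H[a]
            W[:, a] = -W[:, a]
    residual = 0.5 * float((s[k:] ** 2).sum())
    return FactorizationResult(
        W=W,
        H=H,
        k=k,
        objective_trace=np.asarray([residual]),
        method="pca",
        seed=None,
        restarts=1,
        converged=True,
        row_labels=row_labels,
        col_labels=col_labels,
        col_mean=None,
    )


def reconstruct(result: FactorizationResult) -> DataMatrix:
    """The model's approximation ``W H`` (plus the stored mean for PCA)."""
    values = result.W @ result.H
    if result.col_mean is not None:
        values = values + result.col_mean[None, :]
    return DataMatrix(values, result.row_labels, result.col_labels)
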