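"""1-D thresholding of factor scores and loadings into memberships.

Each factor of a factorization gives a continuous score per sample
(``W[:, a]``) and loading per variable (``H[a, :]``).  Turning a factor into
a bicluster means deciding which samples/variables are "in", which is a
classic two-class 1-D segmentation problem.  Four classical criteria are
provided:

- ``otsu``      — maximize between-class variance of the histogram;
- ``maxen``     — Kapur's criterion: maximize the summed Shannon entropies of
  the foreground and background histogram distributions;
- ``iter``      — Ridler–Calvard iterative selection: fixed point of
  ``t = (mean(values > t) + mean(values <= t)) / 2`` started at the mean;
- ``fcm``       — two-class fuzzy c-means on the raw values; members are the
  points whose membership in the higher-mean class exceeds 0.5.

Every method first min-max scales the vector to [0, 1] (so results are
invariant to positive affine rescaling) and counts as members the values
strictly above the threshold.  A constant vector has no meaningful split and
yields an empty mask with a warning, uniformly across methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import Bicluster, BiclusterSet
from .factorize import FactorizationResult

__all__ = [
    "ThresholdSpec",
    "MembershipVector",
    "otsu_threshold",
    "maxent_threshold",
    "iterative_threshold",
    "fcm_membership",
    "apply_threshold",
    "extract_biclusters",
]

METHODS = ("otsu", "fcm", "iter", "maxen")


@dataclass(frozen=True)
class ThresholdSpec:
    """Choice of thresholding algorithm and its knobs.

    ``n_bins`` is the histogram resolution for the otsu/maxen criteria
    (256 by convention for values scaled to [0, 1]).  ``fcm_fuzzifier`` is
    the fuzzy c-means exponent (> 1; 2.0 standard).
    """

    method: str = "otsu"
    n_bins: int = 256
    fcm_fuzzifier: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    iter_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.fcm_fuzzifier <= 1:
            raise ValueError("fcm_fuzzifier must be > 1")


@dataclass
class MembershipVector:
    """Boolean membership mask over a score/loading vector.

    ``threshold`` is in the original units of ``values`` for the
    threshold-based methods and ``None`` for fcm (which has no single
    cut-point).
    """

    mask: np.ndarray
    threshold: float | None
    values: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def _prepare(values) -> tuple[np.ndarray, np.ndarray | None, float, float]:
    """Return (values, scaled-or-None, lo, span); scaled is None if degenerate."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    lo = float(v.min())
    hi = float(v.max())
    if hi <= lo:
        return v, None, lo, 0.0
    return v, (v - lo) / (hi - lo), lo, hi - lo


def _empty(v: np.ndarray, why: str) -> MembershipVector:
    warnings.warn(f"{why}; returning an empty membership mask", stacklevel=3)
    return MembershipVector(np.zeros(v.size, dtype=bool), None, v)


def _hist(scaled: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(scaled, bins=n_bins, range=(0.0, 1.0))
    return counts.astype(float), edges


def otsu_threshold(values, n_bins: int = 256) -> MembershipVector:
    """Histogram threshold maximizing between-class variance."""
    v, scaled, lo, span = _prepare(values)
    if scaled is None:
        return _empty(v, "constant vector")
    counts, edges = _hist(scaled, n_bins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]  # background weight at cut after bin t
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)[:-1]
    total_mean = float((p * centers).sum())
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        return _empty(v, "all mass in one histogram bin")
    mu0 = np.where(valid, cum_mean / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (total_mean - cum_mean) / np.where(w1 > 0, w1, 1.0), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    cut = int(np.argmax(between))
    t_scaled = edges[cut + 1]
    mask = scaled > t_scaled
    return MembershipVector(mask, lo + t_scaled * span, v)


def maxent_threshold(values, n_bins: int = 256) -> MembershipVector:
    """Kapur's maximum-entropy histogram threshold."""
    v, scaled, lo, span = _prepare(values)
    if scaled is None:
        return _empty(v, "constant vector")
    counts, edges = _hist(scaled, n_bins)
    p = counts / counts.sum()
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    # class entropies; empty classes are invalid cuts
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)[:-1]
    total_plogp = float(plogp.sum())
    valid = (P0 > 0) & (P1 > 0)
    if not valid.any():
        return _empty(v, "all mass in one histogram bin")
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(np.where(P0 > 0, P0, 1.0)) - cum_plogp / np.where(P0 > 0, P0, 1.0)
        h1 = np.log(np.where(P1 > 0, P1, 1.0)) - (total_plogp - cum_plogp) / np.where(
            P1 > 0, P1, 1.0
        )
    score = np.where(valid, h0 + h1, -np.inf)
    cut = int(np.argmax(score))
    t_scaled = edges[cut + 1]
    mask = scaled > t_scaled
    return MembershipVector(mask, lo + t_scaled * span, v)


def iterative_threshold(values, tol: float = 1e-8, max_iter: int = 500) -> MembershipVector:
    """Ridler–Calvard iterative selection threshold.

    Starting from the global mean, the threshold is moved to the midpoint of
    the two class means until it stabilizes.  Because the iteration is
    affine-equivariant it is run on the min-max scaled vector, and the fixed
    point is mapped back to the original units.
    """
    v, scaled, lo, span = _prepare(values)
    if scaled is None:
        return _empty(v, "constant vector")
    t = float(scaled.mean())
    for _ in range(max_iter):
        above = scaled > t
        # with >= 2 distinct values and t strictly inside (0, 1), both
        # classes are non-empty: min <= t < max
        hi_mean = float(scaled[above].mean()) if above.any() else t
        lo_mean = float(scaled[~above].mean()) if (~above).any() else t
        t_new = 0.5 * (hi_mean + lo_mean)
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    mask = scaled > t
    return MembershipVector(mask, lo + t * span, v)


def fcm_membership(
    values,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
) -> MembershipVector:
    """Two-class fuzzy c-means membership on a 1-D vector.

    Centers are initialized deterministically at the min and max of the
    scaled values (``seed`` is accepted for interface symmetry but unused).
    A point is a member when its fuzzy membership in the higher-mean class
    exceeds 0.5.
    """
    del seed
    v, scaled, _, _ = _prepare(values)
    if scaled is None:
        return _empty(v, "constant vector")
    expo = 2.0 / (fuzzifier - 1.0)
    centers = np.array([0.0, 1.0])
    u = np.empty((scaled.size, 2))
    for _ in range(max_iter):
        d = np.abs(scaled[:, None] - centers[None, :])
        exact = d < 1e-15
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        hit = exact.any(axis=1)
        if hit.any():
            u[hit] = exact[hit].astype(float)
            u[hit] /= u[hit].sum(axis=1, keepdims=True)
        um = u**fuzzifier
        denom = um.sum(axis=0)
        new_centers = (um * scaled[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0)
        if np.max(np.abs(new_centers - centers)) < tol:
            centers = new_centers
            break
        centers = new_centers
    high = int(np.argmax(centers))
    mask = u[:, high] > 0.5
    return MembershipVector(mask, None, v)


def apply_threshold(values, spec: ThresholdSpec) -> MembershipVector:
    """Dispatch to the method named in ``spec``."""
    if spec.method == "otsu":
        return otsu_threshold(values, n_bins=spec.n_bins)
    if spec.method == "maxen":
        return maxent_threshold(values, n_bins=spec.n_bins)
    if spec.method == "iter":
        return iterative_threshold(values, tol=spec.iter_tol)
    if spec.method == "fcm":
        return fcm_membership(
            values,
            fuzzifier=spec.fcm_fuzzifier,
            tol=spec.fcm_tol,
            max_iter=spec.fcm_max_iter,
        )
    raise ValueError(f"unknown method {spec.method!r}")


def extract_biclusters(
    result: FactorizationResult, spec: ThresholdSpec | None = None
) -> BiclusterSet:
    """Threshold every factor's scores and loadings into a bicluster set.

    Factor ``a`` contributes the bicluster (members of ``W[:, a]``, members
    of ``H[a, :]``).  PCA factors are thresholded on their signed values
    after the deterministic sign fix (dominant side positive): a mixed
    factor then contributes only its dominant-side members, whereas folding
    with ``abs`` would merge the two sign groups into one spurious
    bicluster.  NMF factors are thresholded on the raw nonnegative values.
    A factor whose row or column mask comes out empty yields no bicluster;
    output order follows factor order.
    """
    spec = spec or ThresholdSpec()
    out: list[Bicluster] = []
    for a in range(result.k):
        scores = result.W[:, a]
        loadings = result.H[a, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = apply_threshold(scores, spec)
            cols = apply_threshold(loadings, spec)
        if rows.mask.any() and cols.mask.any():
            out.append(
                Bicluster(frozenset(rows.indices.tolist()), frozenset(cols.indices.tolist()))
            )
    return BiclusterSet(out)
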