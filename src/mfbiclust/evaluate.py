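"""Bicluster match scores: how well a found set matches a reference set.

The dimension match score of a set ``M1`` against ``M2`` is the mean, over
the index sets of ``M1``, of the best Jaccard similarity achieved against
any index set of ``M2``:

    S(M1, M2) = (1/|M1|) * sum_{b1 in M1} max_{b2 in M2} |b1 ∩ b2| / |b1 ∪ b2|

computed separately over sample (row) sets and variable (column) sets; the
overall score is their product.  With ``E`` the planted truth and ``F`` the
found set, ``S(E, F)`` is the recovery score (did we find everything that is
there?) and ``S(F, E)`` the relevance score (is everything we found real?).
All scores live in [0, 1] and equal 1 exactly on perfect agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import BiclusterSet

__all__ = ["MatchReport", "dimension_match_score", "overall_match_score"]


def _jaccard(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 0.0  # cannot arise for planted truth; defined for safety
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def dimension_match_score(M1: list[set[int]], M2: list[set[int]]) -> float:
    """Mean best-Jaccard of each index set in ``M1`` against ``M2``.

    Returns 0 when ``M2`` is empty; raises when ``M1`` is empty (the mean
    over nothing is undefined).
    """
    M1 = [set(s) for s in M1]
    M2 = [set(s) for s in M2]
    if not M1:
        raise ValueError("M1 must be non-empty (mean over an empty set)")
    if not M2:
        return 0.0
    return float(np.mean([max(_jaccard(b1, b2) for b2 in M2) for b1 in M1]))


@dataclass
class MatchReport:
    """Full scorecard of a found bicluster set against a reference.

    ``sample_score`` and ``variable_score`` are the row/column dimension
    scores of found-vs-truth; ``overall`` is their product (this is the
    relevance direction).  ``recovery`` is the analogous product computed
    truth-vs-found.  ``per_bicluster_best_match`` lists, for each found
    bicluster, the truth index it matches best and the product of row and
    column Jaccards there.
    """

    sample_score: float
    variable_score: float
    overall: float
    recovery: float
    relevance: float
    per_bicluster_best_match: list[tuple[int, float]]

    def to_dict(self) -> dict:
        return {
            "sample_score": self.sample_score,
            "variable_score": self.variable_score,
            "overall": self.overall,
            "recovery": self.recovery,
            "relevance": self.relevance,
            "per_bicluster_best_match": [
                {"truth_index": i, "jaccard_product": s}
                for i, s in self.per_bicluster_best_match
            ],
        }


def overall_match_score(found: BiclusterSet, truth: BiclusterSet) -> MatchReport:
    """Score ``found`` against ``truth`` in both directions.

    An empty found set scores 0 everywhere (with a warning) rather than
    erroring: at high noise a method can legitimately return nothing.
    """
    if truth.k == 0:
        raise ValueError("truth bicluster set must be non-empty")
    if found.k == 0:
        warnings.warn("found bicluster set is empty; all scores are 0", stacklevel=2)
        return MatchReport(0.0, 0.0, 0.0, 0.0, 0.0, [])
    fr, fc = found.row_sets(), found.col_sets()
    tr, tc = truth.row_sets(), truth.col_sets()
    sample = dimension_match_score(fr, tr)
    variable = dimension_match_score(fc, tc)
    overall = sample * variable
    recovery = dimension_match_score(tr, fr) * dimension_match_score(tc, fc)
    best: list[tuple[int, float]] = []
    for rows, cols in zip(fr, fc):
        scores = [
            _jaccard(rows, t_rows) * _jaccard(cols, t_cols)
            for t_rows, t_cols in zip(tr, tc)
        ]
        idx = int(np.argmax(scores))
        best.append((idx, float(scores[idx])))
    return MatchReport(
        sample_score=sample,
        variable_score=variable,
        overall=overall,
        recovery=recovery,
        relevance=overall,
        per_bicluster_best_match=best,
    )
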