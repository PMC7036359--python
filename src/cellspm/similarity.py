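"""Spectral similarity measures on aligned intensity vectors.

Three measures are supported, all bounded in [0, 1] on non-negative
vectors, symmetric, equal to 1 when the vectors are identical and 0 when
their supports are disjoint:

``Cos``
    cosine similarity, sum(a*b) / (||a|| * ||b||).
``Eu``
    relative Euclidean similarity, 1 - ||a-b||^2 / (||a||^2 + ||b||^2),
    equivalently 2<a,b> / (||a||^2 + ||b||^2).
``iEu``
    intensity-weighted relative Euclidean similarity: the same ratio with
    per-coordinate weights w_i = a_i + b_i, which up-weights agreement on
    intense peaks.

Each measure is registered behind one interface so an alternative
formulation can be dropped in without touching the search pipeline.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .matching import MatchParams, aligned_vectors, match_peaks
from .peaks import PeakList

__all__ = ["cos_score", "eu_score", "ieu_score", "MEASURES", "score_pair", "score_vectors"]


def _check(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be one-dimensional and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("vectors must be non-negative")
    if not np.any(a > 0) or not np.any(b > 0):
        raise ValueError("similarity undefined for an all-zero vector")
    return a, b


def cos_score(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; 1.0 for proportional vectors, 0.0 for disjoint support."""
    a, b = _check(a, b)
    score = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return min(score, 1.0)  # guard against rounding just above 1


def eu_score(a: np.ndarray, b: np.ndarray) -> float:
    """Relative Euclidean similarity: 2<a,b> / (||a||^2 + ||b||^2)."""
    a, b = _check(a, b)
    return float(2.0 * (a @ b) / (a @ a + b @ b))


def ieu_score(a: np.ndarray, b: np.ndarray) -> float:
    """Intensity-weighted relative Euclidean similarity with weights a_i + b_i."""
    a, b = _check(a, b)
    w = a + b
    num = float(w @ ((a - b) ** 2))
    den = float(w @ (a**2 + b**2))
    return 1.0 - num / den


MEASURES: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "Cos": cos_score,
    "Eu": eu_score,
    "iEu": ieu_score,
}


def score_vectors(a: np.ndarray, b: np.ndarray, measure: str) -> float:
    try:
        fn = MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}") from None
    return fn(a, b)


def score_pair(
    query: PeakList,
    reference: PeakList,
    measure: str,
    params: MatchParams = MatchParams(),
) -> float:
    """Similarity of two (base-peak normalized) spectra under one measure.

    Composes ppm peak matching, aligned-vector construction and the chosen
    measure; returns a score in [0, 1].
    """
    if query.n_peaks == 0 or reference.n_peaks == 0:
        raise ValueError("cannot score an empty peak list")
    a = match_peaks(query, reference, params)
    vec_q, vec_r = aligned_vectors(query, reference, a)
    return score_vectors(vec_q, vec_r, measure)
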