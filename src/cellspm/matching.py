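"""Peak alignment between a query and a reference spectrum.

Two peaks may be paired when the query m/z lies within a relative (ppm)
window of the reference m/z; the window half-width is computed from the
reference side, treating the database as the calibrated standard. Among
all feasible one-to-one matchings the aligner returns the one with maximum
cardinality and, among those, minimum total |Delta m/z|; ties are broken
deterministically in favour of lower reference m/z, then lower query m/z.

The assignment is solved exactly (Jonker-Volgenant via scipy) on the
connected components of the candidate-pair graph. With realistic ppm
tolerances almost every component is a single pair, so the exact solve
costs the same as a nearest-neighbour sweep but is order-independent and
optimal even in crowded m/z regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .peaks import PeakList

__all__ = ["MatchParams", "Alignment", "match_peaks", "aligned_vectors", "alignment_table"]

#: default matching tolerances: high-resolution spectra use +/- 5 ppm,
#: integer-mass spectra +/- 500 ppm (at m/z <= 1000 that is at most
#: +/- 0.5, i.e. exact integer equality)
HIGHRES_TOL_PPM = 5.0
INTEGER_TOL_PPM = 500.0


@dataclass(frozen=True)
class MatchParams:
    """Relative mass tolerance for peak pairing."""

    tol_ppm: float = HIGHRES_TOL_PPM

    def __post_init__(self) -> None:
        if not self.tol_ppm > 0:
            raise ValueError("tol_ppm must be > 0")


@dataclass(frozen=True)
class Alignment:
    """A one-to-one pairing of query and reference peak indices.

    ``pairs`` is an integer array of shape (k, 2) holding (query index,
    reference index) rows; ``query_only`` and ``ref_only`` hold the
    unmatched indices. Every index of either spectrum appears exactly once
    across the three containers.
    """

    pairs: np.ndarray
    query_only: np.ndarray
    ref_only: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


def _candidate_edges(
    query: PeakList, reference: PeakList, tol_ppm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (query, reference) index pairs within tolerance, plus |Delta mz|."""
    qmz, rmz = query.mz, reference.mz
    if qmz.size == 0 or rmz.size == 0:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty, np.empty(0)
    half = tol_ppm * 1e-6 * rmz
    lo = rmz - half
    hi = rmz + half
    j_lo = np.searchsorted(hi, qmz, side="left")
    j_hi = np.searchsorted(lo, qmz, side="right")
    counts = np.maximum(j_hi - j_lo, 0)
    qi = np.repeat(np.arange(qmz.size, dtype=np.intp), counts)
    if qi.size == 0:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty, np.empty(0)
    # reference indices: for each query, the run j_lo[i] .. j_hi[i]-1
    offsets = np.concatenate(([0], np.cumsum(counts)))
    rj = np.empty(qi.size, dtype=np.intp)
    for i in np.nonzero(counts)[0]:
        rj[offsets[i] : offsets[i + 1]] = np.arange(j_lo[i], j_hi[i])
    delta = np.abs(qmz[qi] - rmz[rj])
    return qi, rj, delta


def _solve_component(
    qi: np.ndarray, rj: np.ndarray, delta: np.ndarray
) -> list[tuple[int, int]]:
    """Exact min-cost max-cardinality assignment on one candidate component."""
    qs = np.unique(qi)
    rs = np.unique(rj)
    q_pos = {int(q): k for k, q in enumerate(qs)}
    r_pos = {int(r): k for k, r in enumerate(rs)}
    big = float(delta.sum()) + 1.0
    cost = np.full((qs.size, rs.size), big)
    for q, r, d in zip(qi, rj, delta):
        # epsilon terms realize the tie rule: lower reference m/z first,
        # then lower query m/z (component indices are m/z ordered)
        cost[q_pos[int(q)], r_pos[int(r)]] = d + 1e-9 * r_pos[int(r)] + 1e-12 * q_pos[int(q)]
    rows, cols = linear_sum_assignment(cost)
    out = []
    for a, b in zip(rows, cols):
        if cost[a, b] < big:
            out.append((int(qs[a]), int(rs[b])))
    return out


def match_peaks(query: PeakList, reference: PeakList, params: MatchParams) -> Alignment:
    """Align query peaks to reference peaks under a ppm tolerance.

    Either list may be empty, in which case every index is unmatched.
    Deterministic for fixed input.
    """
    qi, rj, delta = _candidate_edges(query, reference, params.tol_ppm)
    pairs: list[tuple[int, int]]
    if qi.size == 0:
        pairs = []
    else:
        q_deg = np.bincount(qi, minlength=query.n_peaks)
        r_deg = np.bincount(rj, minlength=reference.n_peaks)
        if q_deg.max() == 1 and r_deg.max() == 1:
            # every candidate pair is independent: accept all
            pairs = list(zip(qi.tolist(), rj.tolist()))
        else:
            pairs = []
            # connected components over the candidate graph; edges are
            # sorted by query index and m/z is monotone, so components are
            # contiguous runs of edges sharing query or reference indices
            parent = list(range(qi.size))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            by_q: dict[int, int] = {}
            by_r: dict[int, int] = {}
            for e in range(qi.size):
                for table, key in ((by_q, int(qi[e])), (by_r, int(rj[e]))):
                    if key in table:
                        ra, rb = find(table[key]), find(e)
                        if ra != rb:
                            parent[rb] = ra
                    else:
                        table[key] = e
            comps: dict[int, list[int]] = {}
            for e in range(qi.size):
                comps.setdefault(find(e), []).append(e)
            for edges in comps.values():
                idx = np.asarray(edges, dtype=np.intp)
                if idx.size == 1:
                    pairs.append((int(qi[idx[0]]), int(rj[idx[0]])))
                else:
                    pairs.extend(_solve_component(qi[idx], rj[idx], delta[idx]))
    pairs.sort()
    pair_arr = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    matched_q = np.zeros(query.n_peaks, dtype=bool)
    matched_r = np.zeros(reference.n_peaks, dtype=bool)
    matched_q[pair_arr[:, 0]] = True
    matched_r[pair_arr[:, 1]] = True
    return Alignment(
        pairs=pair_arr,
        query_only=np.nonzero(~matched_q)[0],
        ref_only=np.nonzero(~matched_r)[0],
    )


def aligned_vectors(
    query: PeakList, reference: PeakList, a: Alignment
) -> tuple[np.ndarray, np.ndarray]:
    """Paired intensity vectors over matched pairs and unmatched peaks.

    A matched pair contributes (query intensity, reference intensity); an
    unmatched query peak contributes (intensity, 0) and an unmatched
    reference peak (0, intensity). Vector length is
    ``n_pairs + len(query_only) + len(ref_only)`` and each vector sums to
    the total intensity of its spectrum.
    """
    n_idx = a.pairs.shape[0] + a.query_only.size + a.ref_only.size
    q_seen = np.concatenate((a.pairs[:, 0], a.query_only))
    r_seen = np.concatenate((a.pairs[:, 1], a.ref_only))
    if (
        np.unique(q_seen).size != query.n_peaks
        or np.unique(r_seen).size != reference.n_peaks
        or q_seen.size != a.pairs.shape[0] + a.query_only.size
    ):
        raise ValueError("alignment is inconsistent with the given peak lists")
    vec_q = np.zeros(n_idx)
    vec_r = np.zeros(n_idx)
    k = a.pairs.shape[0]
    vec_q[:k] = query.intensity[a.pairs[:, 0]]
    vec_r[:k] = reference.intensity[a.pairs[:, 1]]
    vec_q[k : k + a.query_only.size] = query.intensity[a.query_only]
    vec_r[k + a.query_only.size :] = reference.intensity[a.ref_only]
    return vec_q, vec_r


def alignment_table(query: PeakList, reference: PeakList, a: Alignment) -> pd.DataFrame:
    """Diagnostic table of matched pairs: query m/z, reference m/z, delta ppm."""
    qmz = query.mz[a.pairs[:, 0]]
    rmz = reference.mz[a.pairs[:, 1]]
    return pd.DataFrame(
        {
            "query_mz": qmz,
            "ref_mz": rmz,
            "delta_ppm": (qmz - rmz) / rmz * 1e6,
        }
    )
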