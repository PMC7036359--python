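"""Database search, leave-one-out evaluation, and bootstrap confidence.

Identification is by spectral pattern matching: a query spectrum is scored
against every eligible reference in the database and the reference with
the highest score (the *top hit*) supplies the predicted label. The
confidence of a prediction is estimated by resampling the query's peaks
with replacement (bootstrap) and measuring how often the replicates'
top-hit label agrees with the original one.

References are always stratified by acquisition polarity — positive- and
negative-mode spectra are never compared — and a query is never scored
against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .database import SpectralDatabase, SpectrumRecord
from .matching import MatchParams, aligned_vectors, match_peaks
from .peaks import PeakList
from .similarity import MEASURES, score_vectors

__all__ = [
    "SpmConfig",
    "Hit",
    "MatchResult",
    "ConfidenceResult",
    "QueryOutcome",
    "eligible_references",
    "search",
    "loo_evaluate",
    "loo_evaluate_multi",
    "bootstrap_spectrum",
    "confidence_score",
    "confidence_scores_multi",
    "results_table",
]


@dataclass(frozen=True)
class SpmConfig:
    """Configuration of one search/evaluation run.

    ``level`` selects the label used for correctness ('genus' or
    'species'); species-level runs restrict both queries and references to
    records carrying a species label, so genus-only field isolates take
    part only at the genus level.
    """

    measure: str = "Cos"
    tol_ppm: float = 5.0
    level: str = "genus"
    polarity: str = "positive"
    n_bootstrap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {sorted(MEASURES)}")
        if self.level not in ("genus", "species"):
            raise ValueError("level must be 'genus' or 'species'")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not self.tol_ppm > 0:
            raise ValueError("tol_ppm must be > 0")

    @property
    def match_params(self) -> MatchParams:
        return MatchParams(tol_ppm=self.tol_ppm)


@dataclass(frozen=True)
class Hit:
    reference_id: str
    score: float
    genus: str
    species: str | None


@dataclass(frozen=True)
class MatchResult:
    """Ranked scored hits of one query against a database.

    Hits are sorted by score descending, ties broken by reference id
    ascending; the rank-1 entry is the top hit.
    """

    query_id: str
    hits: tuple[Hit, ...]

    @property
    def top_hit(self) -> Hit:
        return self.hits[0]


@dataclass(frozen=True)
class ConfidenceResult:
    query_id: str
    top_hit_label: str
    confidence: float
    n_bootstrap: int
    seed: int


@dataclass(frozen=True)
class QueryOutcome:
    """One leave-one-out verdict: the ranking plus a correctness flag."""

    record: SpectrumRecord
    result: MatchResult | None
    true_label: str
    correct: bool | None  # None when the query was unevaluable

    @property
    def evaluable(self) -> bool:
        return self.result is not None


def eligible_references(
    db: SpectralDatabase, query_id: str | None, cfg: SpmConfig
) -> list[SpectrumRecord]:
    """References sharing the configured polarity and labeled at the level,
    excluding the query itself."""
    return [
        r
        for r in db
        if r.polarity == cfg.polarity
        and r.id != query_id
        and r.label(cfg.level) is not None
    ]


def _rank(refs: list[SpectrumRecord], scores: np.ndarray) -> tuple[Hit, ...]:
    order = sorted(range(len(refs)), key=lambda i: (-scores[i], refs[i].id))
    return tuple(
        Hit(refs[i].id, float(scores[i]), refs[i].genus, refs[i].species) for i in order
    )


def _score_against(
    query_peaks: PeakList,
    refs: list[SpectrumRecord],
    measures: list[str],
    params: MatchParams,
) -> np.ndarray:
    """Score one query against many references for several measures at once.

    The ppm alignment — the expensive step — is computed once per
    reference and shared across measures. Returns (n_refs, n_measures).
    """
    out = np.zeros((len(refs), len(measures)))
    for i, ref in enumerate(refs):
        a = match_peaks(query_peaks, ref.peaks, params)
        vq, vr = aligned_vectors(query_peaks, ref.peaks, a)
        for j, m in enumerate(measures):
            out[i, j] = score_vectors(vq, vr, m)
    return out


def search(query: SpectrumRecord, db: SpectralDatabase, cfg: SpmConfig) -> MatchResult:
    """Score ``query`` against every eligible reference; full ranking.

    Raises if the polarity/label/self-exclusion constraints leave no
    candidate references.
    """
    refs = eligible_references(db, query.id, cfg)
    if not refs:
        raise ValueError(
            f"no eligible references for query {query.id!r}: need records with "
            f"polarity={cfg.polarity!r}, a {cfg.level} label, and id != query id"
        )
    scores = _score_against(query.peaks, refs, [cfg.measure], cfg.match_params)[:, 0]
    return MatchResult(query_id=query.id, hits=_rank(refs, scores))


def loo_evaluate(db: SpectralDatabase, cfg: SpmConfig) -> list[QueryOutcome]:
    """Leave-one-out evaluation: every eligible record queried once against
    the database minus itself."""
    return loo_evaluate_multi(db, cfg, [cfg.measure])[cfg.measure]


def loo_evaluate_multi(
    db: SpectralDatabase, cfg: SpmConfig, measures: list[str]
) -> dict[str, list[QueryOutcome]]:
    """Leave-one-out evaluation for several measures, sharing the per-pair
    peak alignments across measures.

    Records whose exclusion empties the candidate set are recorded as
    unevaluable rather than silently dropped.
    """
    outcomes: dict[str, list[QueryOutcome]] = {m: [] for m in measures}
    queries = eligible_references(db, None, cfg)
    params = cfg.match_params
    for query in queries:
        refs = [r for r in queries if r.id != query.id]
        true_label = query.label(cfg.level)
        assert true_label is not None
        if not refs:
            for m in measures:
                outcomes[m].append(QueryOutcome(query, None, true_label, None))
            continue
        scores = _score_against(query.peaks, refs, measures, params)
        for j, m in enumerate(measures):
            result = MatchResult(query_id=query.id, hits=_rank(refs, scores[:, j]))
            top = result.top_hit
            assert top.reference_id != query.id
            predicted = top.genus if cfg.level == "genus" else top.species
            outcomes[m].append(
                QueryOutcome(query, result, true_label, predicted == true_label)
            )
    return outcomes


def bootstrap_spectrum(p: PeakList, rng: np.random.Generator) -> PeakList:
    """One bootstrap replicate of a spectrum.

    Draws ``n_peaks`` peak indices with replacement; a peak drawn k times
    appears once with k times its original intensity, and the replicate is
    re-normalized to base peak 1.0. The replicate's support is always a
    subset of the original support; on average a fraction 1 - 1/e of the
    peaks survive.
    """
    if p.n_peaks == 0:
        raise ValueError("cannot bootstrap an empty peak list")
    counts = np.bincount(rng.integers(0, p.n_peaks, p.n_peaks), minlength=p.n_peaks)
    keep = counts > 0
    inten = p.intensity[keep] * counts[keep]
    return PeakList(p.mz[keep], inten / inten.max())


def confidence_score(
    query: SpectrumRecord,
    db: SpectralDatabase,
    cfg: SpmConfig,
    rng: np.random.Generator | None = None,
) -> ConfidenceResult:
    """Bootstrap confidence of the query's top-hit label."""
    results = confidence_scores_multi(query, db, cfg, [cfg.measure], rng)
    return results[cfg.measure]


def confidence_scores_multi(
    query: SpectrumRecord,
    db: SpectralDatabase,
    cfg: SpmConfig,
    measures: list[str],
    rng: np.random.Generator | None = None,
) -> dict[str, ConfidenceResult]:
    """Bootstrap confidence for several measures with shared replicates.

    For each of ``cfg.n_bootstrap`` replicates the resampled query is
    searched against the same reference set; the confidence is the
    fraction of replicates whose top-hit label (at ``cfg.level``) equals
    the original query's top-hit label. The same replicate spectra are
    used for every measure, and the per-reference alignment of each
    replicate is computed once.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    refs = eligible_references(db, query.id, cfg)
    if not refs:
        raise ValueError(f"no eligible references for query {query.id!r}")
    params = cfg.match_params
    base_scores = _score_against(query.peaks, refs, measures, params)
    base_labels = {}
    for j, m in enumerate(measures):
        top = _rank(refs, base_scores[:, j])[0]
        base_labels[m] = top.genus if cfg.level == "genus" else top.species
    agree = {m: 0 for m in measures}
    for _ in range(cfg.n_bootstrap):
        rep = bootstrap_spectrum(query.peaks, rng)
        rep_scores = _score_against(rep, refs, measures, params)
        for j, m in enumerate(measures):
            top = _rank(refs, rep_scores[:, j])[0]
            label = top.genus if cfg.level == "genus" else top.species
            if label == base_labels[m]:
                agree[m] += 1
    return {
        m: ConfidenceResult(
            query_id=query.id,
            top_hit_label=str(base_labels[m]),
            confidence=agree[m] / cfg.n_bootstrap,
            n_bootstrap=cfg.n_bootstrap,
            seed=cfg.seed,
        )
        for m in measures
    }


def results_table(
    outcomes: list[QueryOutcome],
    cfg: SpmConfig,
    resolution_mode: str = "highres",
    confidences: dict[str, ConfidenceResult] | None = None,
) -> pd.DataFrame:
    """Flat results table: one row per evaluated query."""
    rows = []
    for o in outcomes:
        if o.result is None:
            continue
        top = o.result.top_hit
        conf = confidences.get(o.record.id) if confidences else None
        rows.append(
            {
                "query_id": o.record.id,
                "true_genus": o.record.genus,
                "true_species": o.record.species or "",
                "hit_id": top.reference_id,
                "hit_genus": top.genus,
                "hit_species": top.species or "",
                "measure": cfg.measure,
                "score": top.score,
                "correct": bool(o.correct),
                "confidence": conf.confidence if conf else np.nan,
                "n_bootstrap": cfg.n_bootstrap if conf else 0,
                "polarity": cfg.polarity,
                "level": cfg.level,
                "resolution_mode": resolution_mode,
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)
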