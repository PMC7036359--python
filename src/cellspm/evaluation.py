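"""Classifier assessment for spectral pattern matching.

The identification pipeline is assessed as a binary decision problem: a
query whose top hit carries the correct label is a positive, a
misidentified query a negative, and the classifier score (a similarity
score or a bootstrap confidence) is the decision variable. This module
provides confusion matrices, overall accuracy with an exact binomial
confidence interval, ROC curves with the Mann-Whitney (rank) AUC, a
qualitative AUC rating, and sensitivity/error-rate threshold tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import beta

from .database import SpectralDatabase
from .search import (
    QueryOutcome,
    SpmConfig,
    confidence_scores_multi,
    loo_evaluate_multi,
    results_table,
)

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "confusion_matrix",
    "overall_accuracy",
    "roc_curve",
    "auc_rating",
    "sensitivity_error_table",
    "ReportEntry",
    "EvalReport",
    "run_report",
    "write_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true label (rows) versus predicted label (columns)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(outcomes: list[QueryOutcome], level: str) -> ConfusionMatrix:
    """Tally true versus predicted labels at a taxonomic level.

    The label set is the sorted union of observed true and predicted
    labels, so a label appearing only among predictions gets a zero-count
    true row.
    """
    pairs = []
    for o in outcomes:
        if o.result is None:
            continue
        top = o.result.top_hit
        predicted = top.genus if level == "genus" else top.species
        pairs.append((o.true_label, str(predicted)))
    if not pairs:
        raise ValueError("no evaluable results to tally")
    labels = tuple(sorted({t for t, _ in pairs} | {p for _, p in pairs}))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in pairs:
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def overall_accuracy(cm: ConfusionMatrix, conf: float = 0.95) -> tuple[float, float, float]:
    """Overall accuracy (trace / total) with a Clopper-Pearson interval.

    The exact binomial interval is conservative, which is the standard
    choice when reporting confusion-matrix accuracies.
    """
    n = cm.n_total
    if n < 1:
        raise ValueError("empty confusion matrix")
    k = int(np.trace(cm.counts))
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, lo, hi


@dataclass(frozen=True)
class RocCurve:
    """One classifier's ROC curve in false-positive-rate coordinates.

    Thresholds are midpoints between consecutive distinct scores plus
    +/- infinity sentinels, so the curve starts at (0, 0) and ends at
    (1, 1). The AUC is the trapezoidal area, identical to the
    Mann-Whitney probability with ties rank-averaged.
    """

    classifier: str
    thresholds: np.ndarray
    sensitivity: np.ndarray  # true positive rate
    specificity: np.ndarray  # true negative rate
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity


def roc_curve(scores, correct, classifier: str = "") -> RocCurve:
    """ROC of a score for separating correct from incorrect identifications.

    ``correct`` flags the positive class. Requires at least one positive
    and one negative; otherwise the ROC is undefined.
    """
    scores = np.asarray(scores, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if scores.shape != correct.shape or scores.ndim != 1:
        raise ValueError("scores and correctness flags must be 1-d and equal length")
    n_pos = int(correct.sum())
    n_neg = int((~correct).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: single class")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred_pos = scores >= t
        sens[i] = (pred_pos & correct).sum() / n_pos
        spec[i] = (~pred_pos & ~correct).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(classifier=classifier, thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


#: qualitative AUC bands; lower edges inclusive
_AUC_BANDS = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
    (0.5, "fail"),
)


def auc_rating(auc: float) -> str:
    """Word label for an AUC value (excellent/good/fair/poor/fail)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    for edge, label in _AUC_BANDS:
        if auc >= edge:
            return label
    return "worse-than-chance"


def sensitivity_error_table(scores, correct, error_caps=(0.05,)) -> pd.DataFrame:
    """Threshold scores and sensitivities at bounded error rates.

    At a threshold t, sensitivity is the fraction of *all* queries that
    are correct with score >= t, and the error rate is the fraction of
    above-threshold identifications that are wrong. For each cap the
    smallest threshold whose error rate is strictly below the cap is
    reported together with its sensitivity (the smallest qualifying
    threshold maximizes sensitivity). Caps no threshold satisfies yield a
    row flagged unachievable with sensitivity 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if scores.size == 0:
        raise ValueError("no scores given")
    n_total = scores.size
    distinct = np.unique(scores)
    candidates = np.concatenate(([distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0))
    rows = []
    for cap in error_caps:
        found = None
        for t in candidates:  # ascending
            above = scores >= t
            n_above = int(above.sum())
            if n_above == 0:
                continue
            err = int((above & ~correct).sum()) / n_above
            if err < cap:
                found = (float(t), int((above & correct).sum()) / n_total, err)
                break
        if found is None:
            rows.append(
                {"error_cap": cap, "threshold": np.nan, "sensitivity": 0.0,
                 "error_rate": np.nan, "achievable": False}
            )
        else:
            t, sens, err = found
            rows.append(
                {"error_cap": cap, "threshold": t, "sensitivity": sens,
                 "error_rate": err, "achievable": True}
            )
    return pd.DataFrame(rows)


@dataclass
class ReportEntry:
    """Results of one (level, polarity, measure) configuration."""

    level: str
    polarity: str
    measure: str
    n_queries: int
    confusion: ConfusionMatrix | None = None
    accuracy: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    roc_similarity: RocCurve | None = None
    roc_confidence: RocCurve | None = None
    threshold_table: pd.DataFrame | None = None
    threshold_table_confidence: pd.DataFrame | None = None
    results: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    """Bundle of report entries plus the run configuration echo."""

    entries: list[ReportEntry]
    config: dict
    seed: int

    def entry(self, level: str, polarity: str, measure: str) -> ReportEntry:
        for e in self.entries:
            if (e.level, e.polarity, e.measure) == (level, polarity, measure):
                return e
        raise KeyError((level, polarity, measure))


def run_report(
    db: SpectralDatabase,
    levels=("genus", "species"),
    polarities=("positive", "negative"),
    measures=("Cos", "Eu", "iEu"),
    tol_ppm: float = 5.0,
    with_bootstrap: bool = False,
    n_bootstrap: int = 500,
    error_caps=(0.05,),
    seed: int = 0,
) -> EvalReport:
    """Leave-one-out evaluation over a grid of configurations.

    For each (level, polarity) the expensive leave-one-out pass is run
    once for all measures; optional bootstrap confidence scores reuse
    per-query child seeds so results do not depend on evaluation order.
    Failures of individual cells (e.g. an undefined ROC because every
    query was correct) are collected as notes, not raised.
    """
    entries: list[ReportEntry] = []
    for level in levels:
        for polarity in polarities:
            base_cfg = SpmConfig(
                measure=measures[0], tol_ppm=tol_ppm, level=level,
                polarity=polarity, n_bootstrap=n_bootstrap, seed=seed,
            )
            try:
                outcomes_by_measure = loo_evaluate_multi(db, base_cfg, list(measures))
            except ValueError as exc:
                for m in measures:
                    entries.append(
                        ReportEntry(level, polarity, m, 0, notes=[f"evaluation failed: {exc}"])
                    )
                continue
            confidences: dict[str, dict] = {m: {} for m in measures}
            if with_bootstrap:
                queries = [
                    o.record for o in outcomes_by_measure[measures[0]] if o.evaluable
                ]
                seeds = np.random.SeedSequence(seed).spawn(len(queries))
                for q, ss in zip(queries, seeds):
                    rng = np.random.default_rng(ss)
                    per_measure = confidence_scores_multi(q, db, base_cfg, list(measures), rng)
                    for m in measures:
                        confidences[m][q.id] = per_measure[m]
            for m in measures:
                outcomes = outcomes_by_measure[m]
                cfg = SpmConfig(
                    measure=m, tol_ppm=tol_ppm, level=level,
                    polarity=polarity, n_bootstrap=n_bootstrap, seed=seed,
                )
                evaluable = [o for o in outcomes if o.evaluable]
                entry = ReportEntry(level, polarity, m, n_queries=len(evaluable))
                if not evaluable:
                    entry.notes.append("no evaluable queries")
                    entries.append(entry)
                    continue
                entry.results = results_table(
                    outcomes, cfg, db.resolution_mode,
                    confidences[m] if with_bootstrap else None,
                )
                entry.confusion = confusion_matrix(outcomes, level)
                entry.accuracy, entry.ci_low, entry.ci_high = overall_accuracy(entry.confusion)
                scores = entry.results["score"].to_numpy()
                flags = entry.results["correct"].to_numpy()
                try:
                    entry.roc_similarity = roc_curve(scores, flags, classifier=m)
                    entry.threshold_table = sensitivity_error_table(scores, flags, error_caps)
                except ValueError as exc:
                    entry.notes.append(f"similarity ROC: {exc}")
                if with_bootstrap:
                    conf = entry.results["confidence"].to_numpy()
                    try:
                        entry.roc_confidence = roc_curve(
                            conf, flags, classifier=f"{m}-confidence"
                        )
                        entry.threshold_table_confidence = sensitivity_error_table(
                            conf, flags, error_caps
                        )
                    except ValueError as exc:
                        entry.notes.append(f"confidence ROC: {exc}")
                entries.append(entry)
    config = {
        "levels": list(levels),
        "polarities": list(polarities),
        "measures": list(measures),
        "tol_ppm": tol_ppm,
        "with_bootstrap": with_bootstrap,
        "n_bootstrap": n_bootstrap,
        "error_caps": list(error_caps),
        "resolution_mode": db.resolution_mode,
        "n_records": len(db),
    }
    return EvalReport(entries=entries, config=config, seed=seed)


def _plot_entry(entry: ReportEntry, out_dir: Path, stem: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if entry.confusion is not None:
        fig, ax = plt.subplots(figsize=(5, 4.2))
        frame = entry.confusion.to_frame()
        im = ax.imshow(frame.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(frame.index)), frame.index, fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(
            f"{entry.measure} {entry.level} {entry.polarity}\n"
            f"accuracy {entry.accuracy:.3f} "
            f"(95% CI {entry.ci_low:.3f}-{entry.ci_high:.3f})",
            fontsize=8,
        )
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(out_dir / f"{stem}_confusion.png", dpi=120)
        plt.close(fig)
    curves = [c for c in (entry.roc_similarity, entry.roc_confidence) if c is not None]
    if curves:
        fig, ax = plt.subplots(figsize=(4.2, 4))
        for c in curves:
            ax.plot(c.fpr, c.sensitivity, label=f"{c.classifier} (AUC {c.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{entry.level} {entry.polarity}", fontsize=9)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"{stem}_roc.png", dpi=120)
        plt.close(fig)


def write_report(report: EvalReport, out_dir: str | Path, plots: bool = True) -> Path:
    """Write result tables, plots and a run manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    all_results = []
    for entry in report.entries:
        stem = f"{entry.level}_{entry.polarity}_{entry.measure}"
        if entry.results is not None:
            all_results.append(entry.results)
        if entry.confusion is not None:
            entry.confusion.to_frame().to_csv(out / f"{stem}_confusion.csv")
        if entry.threshold_table is not None:
            entry.threshold_table.to_csv(out / f"{stem}_thresholds.csv", index=False)
        if entry.threshold_table_confidence is not None:
            entry.threshold_table_confidence.to_csv(
                out / f"{stem}_thresholds_confidence.csv", index=False
            )
        summary_rows.append(
            {
                "level": entry.level,
                "polarity": entry.polarity,
                "measure": entry.measure,
                "n_queries": entry.n_queries,
                "accuracy": entry.accuracy,
                "ci_low": entry.ci_low,
                "ci_high": entry.ci_high,
                "auc": entry.roc_similarity.auc if entry.roc_similarity else np.nan,
                "auc_rating": auc_rating(entry.roc_similarity.auc)
                if entry.roc_similarity
                else "",
                "auc_confidence": entry.roc_confidence.auc if entry.roc_confidence else np.nan,
                "notes": "; ".join(entry.notes),
            }
        )
        if plots:
            _plot_entry(entry, out, stem)
    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
    if all_results:
        pd.concat(all_results, ignore_index=True).to_csv(out / "results.csv", index=False)
    manifest = {"config": report.config, "seed": report.seed, "accuracy_ci_method": "clopper-pearson"}
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
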