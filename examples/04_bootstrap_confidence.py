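"""Bootstrap confidence scores for top-hit identifications.

Each query's peaks are resampled with replacement; the confidence is the
fraction of replicates whose top-hit label agrees with the original one.
Wrong identifications tend to be unstable under resampling, so their
confidence is lower — which makes confidence a better classifier score
than raw similarity when spectra are noisy.
"""

import numpy as np

from cellspm import (
    PreprocessParams, SpmConfig, SynthConfig, build_database,
    confidence_scores_multi, loo_evaluate, make_dataset, roc_curve,
)

cfg = SynthConfig(n_genera=4, cells_per_species=5, presence_prob=0.6,
                  background_peaks=60, background_intensity=0.6,
                  positive_fraction=1.0, seed=2)
db_raw, _, blank = make_dataset(cfg)
db, _ = build_database(db_raw, blank, PreprocessParams())

spm = SpmConfig(measure="Eu", level="species", polarity="positive",
                n_bootstrap=100, seed=7)
outcomes = [o for o in loo_evaluate(db, spm) if o.evaluable]
seeds = np.random.SeedSequence(7).spawn(len(outcomes))
conf = {}
for o, ss in zip(outcomes, seeds):
    res = confidence_scores_multi(o.record, db, spm, ["Eu"], np.random.default_rng(ss))
    conf[o.record.id] = res["Eu"].confidence

flags = np.array([o.correct for o in outcomes])
scores = np.array([o.result.top_hit.score for o in outcomes])
confs = np.array([conf[o.record.id] for o in outcomes])
print(f"{len(outcomes)} queries, species level, noisy spectra")
print(f"  accuracy: {flags.mean():.3f}")
print(f"  mean confidence of correct hits:   {confs[flags].mean():.3f}")
print(f"  mean confidence of incorrect hits: {confs[~flags].mean():.3f}")
print(f"  AUC of similarity score: {roc_curve(scores, flags).auc:.3f}")
print(f"  AUC of confidence score: {roc_curve(confs, flags).auc:.3f}")
print("The bootstrap confidence separates right from wrong calls better "
      "than the similarity score itself.")
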