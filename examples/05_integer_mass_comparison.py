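"""High-resolution versus integer-mass identification.

Rounding m/z to integers (summing coincident intensities) emulates a
unit-resolution instrument. Matching then uses a 500 ppm window, which at
m/z <= 1000 reduces to exact integer equality. The genus-level accuracy
barely moves, though sparse spectra can collapse to a single peak and are
removed by the minimum-peak filter.
"""

import numpy as np

from cellspm import PreprocessParams, SpmConfig, SynthConfig, build_database, loo_evaluate, make_dataset

cfg = SynthConfig(n_genera=6, cells_per_species=6, seed=5)
db_raw, _, blank = make_dataset(cfg)

for integer, tol in ((False, 5.0), (True, 500.0)):
    db, report = build_database(db_raw, blank, PreprocessParams(), integer=integer)
    flags = []
    for pol in ("positive", "negative"):
        out = loo_evaluate(db, SpmConfig(measure="Eu", level="genus", polarity=pol, tol_ppm=tol))
        flags += [o.correct for o in out if o.evaluable]
    mode = "integer-mass " if integer else "high-res    "
    removed = f", {len(report.removed_ids)} spectra removed by min-peak filter" if report.removed_ids else ""
    print(f"{mode} (±{tol:g} ppm): genus accuracy {np.mean(flags):.3f} "
          f"over {len(flags)} queries{removed}")
print("Unit-mass resolution loses little identification power at this "
      "database size, mirroring the value of simpler instruments.")
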