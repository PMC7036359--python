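import warnings

import numpy as np
import pytest

from cellspm import (
    PeakList,
    PreprocessParams,
    SpectralDatabase,
    SpectrumRecord,
    SynthConfig,
    build_database,
    make_dataset,
)

# the generator legitimately places background peaks up to m/z 1000 and the
# jittered copies can fall epsilon outside the nominal window
warnings.filterwarnings("ignore", message="peaks outside the nominal")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_pair():
    """Two normalized 4-peak spectra with 3 matchable peaks and 1 unmatched
    on each side (at 5 ppm)."""
    query = PeakList([100.0, 250.0, 400.0, 700.0], [1.0, 0.5, 0.25, 0.8])
    ref = PeakList([100.0001, 250.0005, 400.0008, 900.0], [0.9, 0.6, 1.0, 0.3])
    return query, ref


def tiny_records():
    """Three hand-built records in one polarity, two genera."""
    return [
        SpectrumRecord(
            id="A1",
            peaks=PeakList([100.0, 200.0, 300.0], [1.0, 0.5, 0.2]),
            genus="Alpha",
            species="Alpha one",
            polarity="positive",
        ),
        SpectrumRecord(
            id="A2",
            peaks=PeakList([100.0, 200.0, 300.0], [1.0, 0.5, 0.2]),
            genus="Alpha",
            species="Alpha one",
            polarity="positive",
        ),
        SpectrumRecord(
            id="B1",
            peaks=PeakList([150.0, 450.0, 650.0], [1.0, 0.8, 0.4]),
            genus="Beta",
            species="Beta one",
            polarity="positive",
        ),
    ]


@pytest.fixture
def tiny_db():
    return SpectralDatabase(tiny_records())


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial synthetic dataset, preprocessed: 4 genera x 2
    species x 6 cells, both polarities."""
    cfg = SynthConfig(n_genera=4, species_per_genus=2, cells_per_species=6, seed=11)
    db_raw, truth, blank = make_dataset(cfg)
    db, report = build_database(db_raw, blank, PreprocessParams())
    return cfg, db, truth, blank, report
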