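"""Synthetic single-cell spectra with realistic statistical structure.

The generator emulates the features that make single-cell laser
desorption/ionization fingerprints identifiable and hard:

* each species has a metabolic fingerprint of characteristic m/z values
  in the 100-1000 window, concentrated in three bands (most peaks at
  m/z 100-330, a second group at 430-660, and a few intense peaks at
  760-880);
* congeneric species share a genus-core fraction of their fingerprint;
* an individual cell detects each fingerprint peak only with some
  probability, with log-normally dispersed intensity and a small ppm mass
  jitter, on top of random low-intensity background peaks;
* every cell also carries peaks of the growth-medium blank, which the
  preprocessing chain is expected to remove;
* cells are acquired in one of two polarities, each with its own
  per-species fingerprint, and some genera can be marked as field
  isolates identified only to the genus level.

All structure is controlled by :class:`SynthConfig` and a single seed, so
a dataset is reproducible file-for-file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .database import SpectralDatabase, SpectrumRecord
from .io import RecordDescriptor, write_metadata, write_peaklist
from .peaks import PeakList

__all__ = ["SynthConfig", "GroundTruth", "Taxonomy", "make_taxonomy", "make_cell_spectrum", "make_dataset"]

#: minimum spacing between peaks of one fingerprint, as a relative distance
FINGERPRINT_SPACING_PPM = 50.0


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the synthetic taxonomy and spectra.

    Defaults give 9 genera x 2 species x 20 cells = 360 records with
    fingerprints of 80 peaks, 80% of which are shared across a genus.
    """

    n_genera: int = 9
    species_per_genus: int = 2
    cells_per_species: int = 20
    fingerprint_size: int = 80
    genus_share: float = 0.8
    presence_prob: float = 0.85
    intensity_cv: float = 0.5
    mz_jitter_ppm: float = 2.0
    background_peaks: int = 15
    blank_peaks: int = 10
    bands: tuple[tuple[float, float], ...] = ((100.0, 330.0), (430.0, 660.0), (760.0, 880.0))
    band_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    pronounced_band: int = 2  # index of the sparse high-intensity band
    pronounced_boost: float = 5.0
    background_intensity: float = 0.05
    blank_intensity: float = 0.5
    positive_fraction: float = 0.5
    n_field_genera: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.genus_share <= 1.0:
            raise ValueError("genus_share must lie in [0, 1]")
        if not 0.0 < self.presence_prob <= 1.0:
            raise ValueError("presence_prob must lie in (0, 1]")
        for name in ("n_genera", "species_per_genus", "cells_per_species",
                     "fingerprint_size", "background_peaks", "blank_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.bands) != len(self.band_weights):
            raise ValueError("bands and band_weights must have equal length")
        if abs(sum(self.band_weights) - 1.0) > 1e-9:
            raise ValueError("band_weights must sum to 1")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_field_genera > self.n_genera:
            raise ValueError("n_field_genera cannot exceed n_genera")


@dataclass(frozen=True)
class Fingerprint:
    """A species' mean spectrum in one polarity."""

    mz: np.ndarray
    mean_intensity: np.ndarray


@dataclass
class Taxonomy:
    """Genus/species tree with per-(species, polarity) fingerprints."""

    genera: list[str]
    species: dict[str, list[str]]  # genus -> species names
    fingerprints: dict[tuple[str, str], Fingerprint]  # (species, polarity) -> fp


@dataclass
class GroundTruth:
    """True labels per generated record plus the generating fingerprints.

    ``latent_species`` keeps the generating species even for field records
    whose metadata label is withheld (genus-only identification).
    """

    records: pd.DataFrame
    taxonomy: Taxonomy
    blank: PeakList


def _draw_band_mz(cfg: SynthConfig, rng: np.random.Generator, n: int, existing: np.ndarray) -> np.ndarray:
    """Draw n m/z values from the band mixture, >= 50 ppm from each other
    and from ``existing``."""
    chosen: list[float] = []
    taken = list(existing)
    attempts = 0
    widths = np.array([b[1] - b[0] for b in cfg.bands])
    while len(chosen) < n:
        attempts += 1
        if attempts > 200 * max(n, 1) + 1000:
            raise ValueError(
                "cannot place fingerprint peaks with the required spacing; "
                "too many peaks for the configured bands"
            )
        b = rng.choice(len(cfg.bands), p=np.asarray(cfg.band_weights))
        mz = cfg.bands[b][0] + rng.random() * widths[b]
        tol = FINGERPRINT_SPACING_PPM * 1e-6 * mz
        if all(abs(mz - t) > tol for t in taken):
            chosen.append(mz)
            taken.append(mz)
    return np.asarray(chosen)


def _mean_intensities(cfg: SynthConfig, rng: np.random.Generator, mz: np.ndarray) -> np.ndarray:
    """Log-normal mean intensities; peaks in the sparse high-m/z band are
    boosted so that band carries few but pronounced signals."""
    means = rng.lognormal(mean=0.0, sigma=1.0, size=mz.size)
    lo, hi = cfg.bands[cfg.pronounced_band]
    means[(mz >= lo) & (mz <= hi)] *= cfg.pronounced_boost
    return means


def make_taxonomy(cfg: SynthConfig, rng: np.random.Generator) -> Taxonomy:
    """Draw genus-core and species-private fingerprint peaks.

    Per genus and polarity, a core of ``round(genus_share *
    fingerprint_size)`` peaks is shared by all congeneric species; each
    species adds its own private peaks up to ``fingerprint_size``. All
    peaks of one fingerprint are at least 50 ppm apart.
    """
    n_core = int(round(cfg.genus_share * cfg.fingerprint_size))
    n_private = cfg.fingerprint_size - n_core
    genera = [f"Genus{g + 1:02d}" for g in range(cfg.n_genera)]
    species = {
        g: [f"{g}_sp{s + 1}" for s in range(cfg.species_per_genus)] for g in genera
    }
    fingerprints: dict[tuple[str, str], Fingerprint] = {}
    for g in genera:
        for polarity in ("positive", "negative"):
            core_mz = _draw_band_mz(cfg, rng, n_core, np.empty(0))
            core_mean = _mean_intensities(cfg, rng, core_mz)
            for sp in species[g]:
                priv_mz = _draw_band_mz(cfg, rng, n_private, core_mz)
                priv_mean = _mean_intensities(cfg, rng, priv_mz)
                mz = np.concatenate((core_mz, priv_mz))
                mean = np.concatenate((core_mean, priv_mean))
                order = np.argsort(mz)
                fingerprints[(sp, polarity)] = Fingerprint(mz[order], mean[order])
    return Taxonomy(genera=genera, species=species, fingerprints=fingerprints)


def make_blank(cfg: SynthConfig, rng: np.random.Generator) -> PeakList:
    """The medium blank: a fixed peak set carried by every cell spectrum."""
    if cfg.blank_peaks == 0:
        return PeakList(np.empty(0), np.empty(0))
    mz = np.sort(100.0 + rng.random(cfg.blank_peaks) * 900.0)
    inten = cfg.blank_intensity * rng.lognormal(0.0, 0.3, cfg.blank_peaks)
    return PeakList(mz, inten)


def make_cell_spectrum(
    fingerprint: Fingerprint,
    cfg: SynthConfig,
    rng: np.random.Generator,
    blank: PeakList | None = None,
) -> PeakList:
    """One cell's raw spectrum drawn from a species fingerprint.

    Each fingerprint peak is detected with probability ``presence_prob``;
    a detected peak's intensity is its mean times a log-normal factor
    (sigma = ``intensity_cv``) and its m/z is jittered uniformly within
    +/- ``mz_jitter_ppm``. Uniform low-intensity background peaks and the
    blank peaks (with the same jitter) are added on top. The spectrum is
    *not* normalized here; base-peak normalization belongs to the
    preprocessing chain.
    """
    if fingerprint.mz.size == 0:
        raise ValueError("fingerprint must be non-empty")
    present = rng.random(fingerprint.mz.size) < cfg.presence_prob
    mz = fingerprint.mz[present]
    inten = fingerprint.mean_intensity[present] * rng.lognormal(
        0.0, cfg.intensity_cv, mz.size
    )
    jitter = (rng.random(mz.size) * 2.0 - 1.0) * cfg.mz_jitter_ppm * 1e-6
    mz = mz * (1.0 + jitter)
    parts_mz = [mz]
    parts_int = [inten]
    if cfg.background_peaks:
        bg_mz = 100.0 + rng.random(cfg.background_peaks) * 900.0
        bg_int = cfg.background_intensity * rng.lognormal(0.0, cfg.intensity_cv, cfg.background_peaks)
        parts_mz.append(bg_mz)
        parts_int.append(bg_int)
    if blank is not None and blank.n_peaks:
        bl_jit = (rng.random(blank.n_peaks) * 2.0 - 1.0) * cfg.mz_jitter_ppm * 1e-6
        parts_mz.append(blank.mz * (1.0 + bl_jit))
        parts_int.append(blank.intensity * rng.lognormal(0.0, 0.2, blank.n_peaks))
    return PeakList(np.concatenate(parts_mz), np.concatenate(parts_int))


def make_dataset(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[SpectralDatabase, GroundTruth, PeakList]:
    """Generate the full labeled raw database, ground truth, and blank.

    Cells of each species are split deterministically between polarities
    according to ``positive_fraction``. The last ``n_field_genera`` genera
    are emitted as field isolates: their records carry no species or
    strain label (identification to genus only), though the ground truth
    retains the generating species. With ``out_dir`` set, the peak lists,
    metadata table, blank spectrum and ground-truth table are written in
    the package's text formats.
    """
    rng = np.random.default_rng(cfg.seed)
    taxonomy = make_taxonomy(cfg, rng)
    blank = make_blank(cfg, rng)
    field_genera = set(taxonomy.genera[len(taxonomy.genera) - cfg.n_field_genera :]) if cfg.n_field_genera else set()
    n_pos = int(round(cfg.cells_per_species * cfg.positive_fraction))
    records: list[SpectrumRecord] = []
    truth_rows: list[dict] = []
    counter = 0
    for g in taxonomy.genera:
        for sp in taxonomy.species[g]:
            strain = f"{sp}_strain1"
            for c in range(cfg.cells_per_species):
                counter += 1
                polarity = "positive" if c < n_pos else "negative"
                peaks = make_cell_spectrum(
                    taxonomy.fingerprints[(sp, polarity)], cfg, rng, blank
                )
                is_field = g in field_genera
                rid = f"SC{counter:05d}"
                records.append(
                    SpectrumRecord(
                        id=rid,
                        peaks=peaks,
                        genus=g,
                        species=None if is_field else sp,
                        strain=None if is_field else strain,
                        polarity=polarity,
                        dataset="field" if is_field else "collection",
                    )
                )
                truth_rows.append(
                    {
                        "id": rid,
                        "genus": g,
                        "species": "" if is_field else sp,
                        "latent_species": sp,
                        "strain": strain,
                        "polarity": polarity,
                        "dataset": "field" if is_field else "collection",
                    }
                )
    db = SpectralDatabase(records)
    truth = GroundTruth(records=pd.DataFrame(truth_rows), taxonomy=taxonomy, blank=blank)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_peaklist(rec.peaks, out / "peaks" / f"{rec.id}.csv")
        write_metadata(
            (
                RecordDescriptor(
                    id=r.id,
                    file=f"peaks/{r.id}.csv",
                    genus=r.genus,
                    species=r.species,
                    strain=r.strain,
                    polarity=r.polarity,
                    dataset=r.dataset,
                )
                for r in records
            ),
            out / "metadata.csv",
        )
        write_peaklist(blank, out / "blank.csv")
        truth.records.to_csv(out / "groundtruth.csv", index=False)
    return db, truth, blank
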