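"""Spectrum records, the spectral database, and database construction.

A :class:`SpectrumRecord` couples one cell's peak list with its identity
labels (genus, optionally species and strain), the acquisition polarity,
and the dataset of origin. A :class:`SpectralDatabase` is a collection of
records sharing one resolution mode (high-resolution or integer-mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import yaml

from .io import (
    DATASETS,
    POLARITIES,
    MetadataError,
    RecordDescriptor,
    read_metadata,
    read_peaklist,
    write_metadata,
    write_peaklist,
)
from .peaks import PeakList, PreprocessParams, preprocess

__all__ = [
    "SpectrumRecord",
    "SpectralDatabase",
    "RESOLUTION_MODES",
    "filter_min_peaks",
    "build_database",
    "load_records",
    "save_database",
    "load_database",
    "PreprocessReport",
]

RESOLUTION_MODES = ("highres", "integer")


@dataclass(frozen=True)
class SpectrumRecord:
    """One database unit: a peak list plus identity labels and polarity."""

    id: str
    peaks: PeakList
    genus: str
    polarity: str
    species: str | None = None
    strain: str | None = None
    dataset: str = "collection"
    resolution_mode: str = "highres"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if self.dataset not in DATASETS:
            raise ValueError(f"dataset must be one of {DATASETS}")
        if self.resolution_mode not in RESOLUTION_MODES:
            raise ValueError(f"resolution_mode must be one of {RESOLUTION_MODES}")
        if self.species is not None and not self.genus:
            raise ValueError("species label requires a genus label")

    def label(self, level: str) -> str | None:
        """The record's label at a taxonomic level ('genus' or 'species')."""
        if level == "genus":
            return self.genus
        if level == "species":
            return self.species
        raise ValueError("level must be 'genus' or 'species'")


class SpectralDatabase:
    """An ordered collection of spectrum records with distinct ids.

    All records share one resolution mode.
    """

    def __init__(self, records: Iterable[SpectrumRecord]):
        self._records: list[SpectrumRecord] = list(records)
        seen: set[str] = set()
        for r in self._records:
            if r.id in seen:
                raise ValueError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
        modes = {r.resolution_mode for r in self._records}
        if len(modes) > 1:
            raise ValueError(f"records mix resolution modes: {sorted(modes)}")
        self._by_id = {r.id: r for r in self._records}

    @property
    def records(self) -> Sequence[SpectrumRecord]:
        return tuple(self._records)

    @property
    def resolution_mode(self) -> str:
        return self._records[0].resolution_mode if self._records else "highres"

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def get(self, record_id: str) -> SpectrumRecord:
        return self._by_id[record_id]

    def subset(self, predicate: Callable[[SpectrumRecord], bool]) -> "SpectralDatabase":
        return SpectralDatabase(r for r in self._records if predicate(r))


def filter_min_peaks(
    db: SpectralDatabase, min_peaks: int
) -> tuple[SpectralDatabase, list[str]]:
    """Drop records with fewer than ``min_peaks`` peaks, reporting their ids.

    Integer-mass conversion can collapse a spectrum to a single peak; such
    spectra carry no pattern and are removed before matching.
    """
    if min_peaks < 1:
        raise ValueError("min_peaks must be >= 1")
    removed = [r.id for r in db if r.peaks.n_peaks < min_peaks]
    kept = SpectralDatabase(r for r in db if r.peaks.n_peaks >= min_peaks)
    return kept, removed


@dataclass
class PreprocessReport:
    """What database construction did to the raw input records."""

    n_input: int = 0
    emptied_ids: list[str] = field(default_factory=list)
    below_min_peaks_ids: list[str] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        return self.emptied_ids + self.below_min_peaks_ids


def build_database(
    records: Iterable[SpectrumRecord],
    blank: PeakList | None,
    params: PreprocessParams = PreprocessParams(),
    integer: bool = False,
) -> tuple[SpectralDatabase, PreprocessReport]:
    """Apply the preprocessing chain to raw records and assemble a database.

    Records emptied by denoising/blank subtraction, or left with fewer than
    ``params.min_peaks`` peaks, are excluded and reported.
    """
    report = PreprocessReport()
    mode = "integer" if integer else "highres"
    processed: list[SpectrumRecord] = []
    for rec in records:
        report.n_input += 1
        peaks = preprocess(rec.peaks, blank, params, integer=integer)
        if peaks is None:
            report.emptied_ids.append(rec.id)
            continue
        processed.append(replace(rec, peaks=peaks, resolution_mode=mode))
    db = SpectralDatabase(processed)
    db, removed = filter_min_peaks(db, params.min_peaks)
    report.below_min_peaks_ids.extend(removed)
    return db, report


def load_records(
    metadata_path: str | Path, base_dir: str | Path | None = None
) -> list[SpectrumRecord]:
    """Load raw records from a metadata table plus per-cell peak-list files.

    Relative file paths in the table are resolved against ``base_dir``
    (default: the metadata table's directory).
    """
    metadata_path = Path(metadata_path)
    base = Path(base_dir) if base_dir is not None else metadata_path.parent
    records = []
    for d in read_metadata(metadata_path):
        fpath = Path(d.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        records.append(
            SpectrumRecord(
                id=d.id,
                peaks=read_peaklist(fpath),
                genus=d.genus,
                species=d.species,
                strain=d.strain,
                polarity=d.polarity,
                dataset=d.dataset,
            )
        )
    return records


def _descriptor(rec: SpectrumRecord) -> RecordDescriptor:
    return RecordDescriptor(
        id=rec.id,
        file=f"peaks/{rec.id}.csv",
        genus=rec.genus,
        species=rec.species,
        strain=rec.strain,
        polarity=rec.polarity,
        dataset=rec.dataset,
    )


def save_database(db: SpectralDatabase, out_dir: str | Path, manifest_extra: dict | None = None) -> Path:
    """Write a database archive: metadata.csv, peaks/<id>.csv, manifest.yaml."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    write_metadata((_descriptor(r) for r in db), out / "metadata.csv")
    for rec in db:
        write_peaklist(rec.peaks, out / "peaks" / f"{rec.id}.csv")
    manifest = {
        "format": "cellspm-database",
        "version": 1,
        "resolution_mode": db.resolution_mode,
        "n_records": len(db),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def load_database(archive_dir: str | Path) -> SpectralDatabase:
    """Load a database archive written by :func:`save_database`."""
    archive_dir = Path(archive_dir)
    manifest_path = archive_dir / "manifest.yaml"
    mode = "highres"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh) or {}
        mode = manifest.get("resolution_mode", "highres")
        if mode not in RESOLUTION_MODES:
            raise MetadataError(f"manifest has unknown resolution_mode {mode!r}")
    records = []
    for d in read_metadata(archive_dir / "metadata.csv"):
        records.append(
            SpectrumRecord(
                id=d.id,
                peaks=read_peaklist(archive_dir / d.file),
                genus=d.genus,
                species=d.species,
                strain=d.strain,
                polarity=d.polarity,
                dataset=d.dataset,
                resolution_mode=mode,
            )
        )
    return SpectralDatabase(records)
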