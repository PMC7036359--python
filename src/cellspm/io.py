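"""Reading and writing peak lists and metadata tables.

Peak-list files are two-column delimited text (m/z, intensity), comma or
tab separated with an optional one-line header, as produced by common
spectrum-processing toolchains. Metadata tables map spectrum identifiers
to files and taxonomic labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .peaks import PeakList

__all__ = [
    "PeakListFormatError",
    "MetadataError",
    "read_peaklist",
    "write_peaklist",
    "RecordDescriptor",
    "read_metadata",
    "write_metadata",
    "read_mzml_centroids",
    "POLARITIES",
    "DATASETS",
]

POLARITIES = ("positive", "negative")
DATASETS = ("collection", "field")


class PeakListFormatError(ValueError):
    """A peak-list file could not be parsed; the message names the line."""


class MetadataError(ValueError):
    """A metadata table violates its column or value contract."""


def _split_line(line: str, sep: str | None) -> tuple[list[str], str | None]:
    if sep is None:
        sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(sep)], sep


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_peaklist(path: str | Path) -> PeakList:
    """Read a two-column (m/z, intensity) delimited text file.

    The delimiter (comma or tab) is autodetected and a single header line
    is skipped if its fields are not numeric. Duplicate m/z rows are merged
    by summing intensity; rows are sorted by m/z. Malformed or non-numeric
    rows raise :class:`PeakListFormatError` naming the offending line.
    """
    path = Path(path)
    mz: list[float] = []
    inten: list[float] = []
    sep: str | None = None
    n_data = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields, sep = _split_line(line, sep)
            if len(fields) != 2:
                raise PeakListFormatError(
                    f"{path.name}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                m, i = float(fields[0]), float(fields[1])
            except ValueError:
                # a header line has *no* numeric fields; anything else is malformed
                if lineno == 1 and n_data == 0 and not any(_is_number(f) for f in fields):
                    continue
                raise PeakListFormatError(
                    f"{path.name}: line {lineno}: non-numeric field in {fields!r}"
                ) from None
            mz.append(m)
            inten.append(i)
            n_data += 1
    if n_data == 0:
        raise PeakListFormatError(f"{path.name}: no peaks found (empty file?)")
    return PeakList(mz, inten)


def write_peaklist(p: PeakList, path: str | Path) -> None:
    """Write a peak list as ``mz,intensity`` CSV with a header line.

    Values are written with shortest exact repr, so read-after-write
    reproduces the peak list bit for bit.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(p.mz.tolist(), p.intensity.tolist()):
            fh.write(f"{m!r},{i!r}\n")


@dataclass(frozen=True)
class RecordDescriptor:
    """One metadata row: where a spectrum lives and what it is."""

    id: str
    file: str
    genus: str
    polarity: str
    species: str | None = None
    strain: str | None = None
    dataset: str = "collection"

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise MetadataError(
                f"unknown polarity {self.polarity!r}; accepted tokens: {POLARITIES}"
            )
        if self.dataset not in DATASETS:
            raise MetadataError(
                f"unknown dataset {self.dataset!r}; accepted tokens: {DATASETS}"
            )


_REQUIRED_COLS = ("id", "file", "genus", "polarity")


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_metadata(path: str | Path) -> list[RecordDescriptor]:
    """Read a delimited metadata table into record descriptors.

    Required columns: id, file, genus, polarity. Optional: species, strain,
    dataset (defaults to "collection"). Duplicate ids and unknown polarity
    or dataset tokens raise :class:`MetadataError`.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise MetadataError(f"{path.name}: missing required column(s) {missing}")
    descriptors: list[RecordDescriptor] = []
    seen: set[str] = set()
    for _, row in table.iterrows():
        rid = _clean(row["id"])
        if rid is None:
            raise MetadataError(f"{path.name}: empty id field")
        if rid in seen:
            raise MetadataError(f"{path.name}: duplicate id {rid!r}")
        seen.add(rid)
        descriptors.append(
            RecordDescriptor(
                id=rid,
                file=_clean(row["file"]) or "",
                genus=_clean(row["genus"]) or "",
                polarity=_clean(row["polarity"]) or "",
                species=_clean(row.get("species")),
                strain=_clean(row.get("strain")),
                dataset=_clean(row.get("dataset")) or "collection",
            )
        )
    return descriptors


def write_metadata(descriptors: Iterable[RecordDescriptor], path: str | Path) -> None:
    rows = [
        {
            "id": d.id,
            "file": d.file,
            "genus": d.genus,
            "species": d.species or "",
            "strain": d.strain or "",
            "polarity": d.polarity,
            "dataset": d.dataset,
        }
        for d in descriptors
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_CV_PROFILE = "MS:1000128"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _decode_binary_array(elem) -> "np.ndarray":
    import base64
    import zlib

    import numpy as np

    accessions = {cv.get("accession") for cv in elem.iter(f"{_MZML_NS}cvParam")}
    binary = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = np.float32 if _CV_32BIT in accessions else np.float64
    return np.frombuffer(raw, dtype=dtype)


def read_mzml_centroids(path: str | Path, index: int = 0) -> PeakList:
    """Read the centroid arrays of one spectrum from an mzML file.

    A deliberately minimal reader: it extracts the m/z and intensity binary
    arrays (64/32-bit floats, optionally zlib-compressed) of the requested
    spectrum and rejects profile-mode spectra — peak picking is out of
    scope. Exotic mzML features (numpress, indexed wrappers with offsets)
    are not handled.
    """
    from lxml import etree

    path = Path(path)
    for i, (_, spectrum) in enumerate(
        etree.iterparse(str(path), tag=f"{_MZML_NS}spectrum")
    ):
        if i != index:
            spectrum.clear()
            continue
        accessions = {
            cv.get("accession")
            for cv in spectrum.findall(f"{_MZML_NS}cvParam")
        }
        if _CV_PROFILE in accessions:
            raise ValueError(
                f"{path.name}: spectrum {index} is profile mode; "
                "only centroided mzML input is supported"
            )
        mz = intensity = None
        for arr in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            arr_acc = {cv.get("accession") for cv in arr.iter(f"{_MZML_NS}cvParam")}
            if _CV_MZ_ARRAY in arr_acc:
                mz = _decode_binary_array(arr)
            elif _CV_INTENSITY_ARRAY in arr_acc:
                intensity = _decode_binary_array(arr)
        if mz is None or intensity is None:
            raise ValueError(f"{path.name}: spectrum {index} lacks m/z or intensity arrays")
        return PeakList(mz, intensity)
    raise ValueError(f"{path.name}: no spectrum at index {index}")
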