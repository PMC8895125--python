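"""Domain types and plain-text I/O for Raman spectra and spectra datasets.

A spectrum lives in a two-column CSV (``raman_shift_cm1,intensity``; ``#``
comments allowed); a dataset is a directory of such files plus a single JSON
manifest whose ``records`` array carries per-spectrum metadata: ``path``,
``chip_id``, ``chip_group`` ("a".."e" or null), ``nominal_ph``, ``ph_tag``,
``replicate`` and ``split`` ("train" | "test" | null).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ManifestError, SpectrumFormatError

CHIP_GROUPS = ("a", "b", "c", "d", "e")

#: column order of the per-spectrum metadata table
LABEL_COLUMNS = ("chip_id", "chip_group", "nominal_ph", "ph_tag", "replicate", "split")


@dataclass
class RamanSpectrum:
    """One acquisition: a shift axis (1/cm), intensities (counts) and metadata.

    ``ph_tag`` is the pH-meter reading attached to the acquisition (the
    training label); ``nominal_ph`` is the grid value of the standard
    solution the acquisition belongs to.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    chip_id: str | None = None
    nominal_ph: float | None = None
    ph_tag: float | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.shifts.shape != self.intensities.shape:
            raise SpectrumFormatError("shifts and intensities must be 1-D and equal length")
        if not np.all(np.isfinite(self.shifts)) or not np.all(np.isfinite(self.intensities)):
            raise SpectrumFormatError("non-finite values in spectrum")
        if np.any(np.diff(self.shifts) == 0):
            raise SpectrumFormatError("duplicate Raman shift values")
        if not np.all(np.diff(self.shifts) > 0):
            order = np.argsort(self.shifts, kind="stable")
            self.shifts = self.shifts[order]
            self.intensities = self.intensities[order]
        if np.any(self.intensities < 0):
            raise SpectrumFormatError("negative intensities")

    def __len__(self) -> int:
        return self.shifts.size


@dataclass
class FeatureVector:
    """Fixed-length model input derived from one spectrum.

    ``values`` is the cropped (and optionally area-normalized) intensity
    window; ``peak1_area`` the internal-standard peak area in counts/cm.
    """

    values: np.ndarray
    peak1_area: float
    chip_id: str | None = None
    chip_group: str | None = None
    nominal_ph: float | None = None
    ph_tag: float | None = None
    replicate: int | None = None
    normalized: bool = False


@dataclass
class SpectraDataset:
    """A collection of spectra with a per-spectrum metadata table.

    ``table`` is a DataFrame aligned with ``spectra`` holding the columns in
    :data:`LABEL_COLUMNS`. ``split`` is "train"/"test" or None; when assigned
    it partitions the dataset.
    """

    spectra: list[RamanSpectrum]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.table):
            raise ManifestError("metadata table length differs from number of spectra")
        missing = [c for c in LABEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ManifestError(f"metadata table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.spectra)

    def counts(self, by: Sequence[str] = ("chip_id", "nominal_ph")) -> pd.Series:
        """Acquisition counts per metadata cell (chip x pH by default)."""
        return self.table.groupby(list(by), dropna=False).size()

    def subset(self, mask: np.ndarray) -> "SpectraDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return SpectraDataset(
            [self.spectra[i] for i in idx], self.table.iloc[idx].reset_index(drop=True)
        )

    @property
    def split(self) -> pd.Series:
        return self.table["split"]


def from_records(pairs: Iterable[tuple[RamanSpectrum, dict]]) -> SpectraDataset:
    """Build a dataset from (spectrum, metadata-dict) pairs."""
    spectra, rows = [], []
    for spec, meta in pairs:
        spectra.append(spec)
        row = {c: meta.get(c) for c in LABEL_COLUMNS}
        rows.append(row)
    return SpectraDataset(spectra, pd.DataFrame(rows, columns=list(LABEL_COLUMNS)))


def read_spectrum(path: str | os.PathLike) -> RamanSpectrum:
    """Read a two-column spectrum CSV; rows are sorted by shift if needed."""
    shifts, intens = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns")
            try:
                shifts.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row") from exc
    if len(set(shifts)) != len(shifts):
        raise SpectrumFormatError(f"{path}: duplicate shift values")
    return RamanSpectrum(np.array(shifts), np.array(intens))


def write_spectrum(spectrum: RamanSpectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as CSV with 6 significant digits on intensities."""
    with open(path, "w") as fh:
        fh.write("# raman_shift_cm1,intensity\n")
        for x, y in zip(spectrum.shifts, spectrum.intensities):
            fh.write(f"{x:.4f},{y:.6g}\n")


def _record(meta: pd.Series, rel_path: str) -> dict:
    def _clean(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        return v

    rep = _clean(meta["replicate"])
    return {
        "path": rel_path,
        "chip_id": _clean(meta["chip_id"]),
        "chip_group": _clean(meta["chip_group"]),
        "nominal_ph": _clean(meta["nominal_ph"]),
        "ph_tag": _clean(meta["ph_tag"]),
        "replicate": int(rep) if rep is not None else None,
        "split": _clean(meta["split"]),
    }


def write_dataset(dataset: SpectraDataset, directory: str | os.PathLike) -> str:
    """Write per-spectrum CSVs plus ``manifest.json``; returns the manifest path.

    ``read_manifest`` inverts this (labels exact, intensities to the printed
    6-significant-digit precision).
    """
    if len(dataset) == 0:
        raise ManifestError("refusing to write an empty dataset")
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    records = []
    width = len(str(len(dataset) - 1))
    for i, (spec, (_, meta)) in enumerate(zip(dataset.spectra, dataset.table.iterrows())):
        rel = f"spectrum_{i:0{width}d}.csv"
        write_spectrum(spec, os.path.join(directory, rel))
        records.append(_record(meta, rel))
    manifest_path = os.path.join(directory, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"records": records}, fh, indent=1)
    return manifest_path


def read_manifest(path: str | os.PathLike) -> SpectraDataset:
    """Load a dataset from a manifest JSON, reading every referenced spectrum."""
    path = os.fspath(path)
    base = os.path.dirname(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "records" not in doc:
        raise ManifestError(f"{path}: no 'records' array")
    pairs = []
    for rec in doc["records"]:
        spec_path = os.path.join(base, rec["path"])
        if not os.path.exists(spec_path):
            raise ManifestError(f"manifest record {rec['path']!r}: file not found")
        spec = read_spectrum(spec_path)
        spec.chip_id = rec.get("chip_id")
        spec.nominal_ph = rec.get("nominal_ph")
        spec.ph_tag = rec.get("ph_tag")
        spec.replicate = rec.get("replicate")
        pairs.append((spec, rec))
    return from_records(pairs)
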