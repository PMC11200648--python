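"""Data model and I/O for NIR spectral sets.

A :class:`SpectrumSet` couples a descending wavenumber axis (cm^-1) with a
records-by-variables intensity matrix and per-record metadata (subject,
instrumental replicate, binary class label; 1 = GDM case, 0 = NGT control).
Intensities are either transflectance-mode reflectance fractions or
absorbance units; conversion is A = log10(1/R).

The full acquisition span is 10,500-4000 cm^-1, conventionally split into
three sub-ranges with distinct noise behaviour: R1 (10,500-7600, high noise),
R2 (7600-5100, varying) and R3 (5100-4000, low noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "RangeName",
    "RANGE_BOUNDS",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "reflectance_to_absorbance",
    "average_replicates",
    "extract_range",
    "default_wavenumber_grid",
]


class SpectraFormatError(ValueError):
    """Raised for malformed spectra/manifest files or inconsistent sets."""


class RangeName(str, Enum):
    """Named wavenumber windows of the acquisition span (cm^-1)."""

    FULL = "Full"
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"


#: Closed interval bounds (high, low) in cm^-1 for each named range. Touching
#: boundaries (7600, 5100) belong to both adjacent ranges.
RANGE_BOUNDS: dict[RangeName, tuple[float, float]] = {
    RangeName.FULL: (10_500.0, 4000.0),
    RangeName.R1: (10_500.0, 7600.0),
    RangeName.R2: (7600.0, 5100.0),
    RangeName.R3: (5100.0, 4000.0),
}


def default_wavenumber_grid(step: float = 2.0) -> np.ndarray:
    """Descending wavenumber axis covering the full span at `step` cm^-1.

    The default 2 cm^-1 spacing gives 3251 points on 10,500-4000 cm^-1.
    """
    high, low = RANGE_BOUNDS[RangeName.FULL]
    n = int(round((high - low) / step)) + 1
    return np.linspace(high, low, n)


@dataclass(frozen=True)
class SpectrumSet:
    """Wavenumber axis + record-by-variable intensity matrix with metadata.

    Parameters
    ----------
    wavenumbers
        Strictly descending axis in cm^-1, one entry per value column.
    values
        2-D array, rows = records (replicates or subject averages).
    unit
        ``"reflectance"`` or ``"absorbance"``.
    meta
        DataFrame aligned with rows; columns ``subject_id``,
        ``replicate_index``, ``label`` (0/1, 1 = GDM).
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    unit: str
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise SpectraFormatError("values must be a 2-D matrix")
        if wn.ndim != 1 or wn.size != vals.shape[1]:
            raise SpectraFormatError(
                f"wavenumber count {wn.size} != value columns {vals.shape[1]}"
            )
        if wn.size > 1 and not np.all(np.diff(wn) < 0):
            raise SpectraFormatError("wavenumbers must be strictly descending")
        if self.unit not in ("reflectance", "absorbance"):
            raise SpectraFormatError(f"unknown unit {self.unit!r}")
        if self.unit == "reflectance" and vals.size and np.nanmin(vals) <= 0:
            raise SpectraFormatError("reflectance values must be > 0")
        required = {"subject_id", "replicate_index", "label"}
        missing = required - set(self.meta.columns)
        if missing:
            raise SpectraFormatError(f"meta missing columns: {sorted(missing)}")
        if len(self.meta) != vals.shape[0]:
            raise SpectraFormatError("meta rows != value rows")
        labels = np.asarray(self.meta["label"])
        if not np.isin(labels, (0, 1)).all():
            raise SpectraFormatError("labels must be 0 or 1")
        dup = self.meta.duplicated(subset=["subject_id", "replicate_index"])
        if dup.any():
            bad = self.meta.loc[dup, ["subject_id", "replicate_index"]]
            raise SpectraFormatError(
                f"duplicated (subject, replicate) pairs: {bad.values.tolist()}"
            )
        per_subject = self.meta.groupby("subject_id")["label"].nunique()
        if (per_subject > 1).any():
            bad_subj = per_subject[per_subject > 1].index.tolist()
            raise SpectraFormatError(f"conflicting labels for subjects {bad_subj}")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Per-record 0/1 label vector."""
        return np.asarray(self.meta["label"], dtype=int)

    def subject_labels(self) -> pd.Series:
        """One label per subject, in first-appearance order."""
        return self.meta.groupby("subject_id", sort=False)["label"].first()


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise SpectraFormatError(f"cannot parse {path}: {exc}") from exc


def read_spectra(
    path: str | Path, manifest: str | Path, unit: str = "reflectance"
) -> SpectrumSet:
    """Read a wide spectra table and its record manifest.

    The spectra file has a ``record_id`` column followed by one column per
    wavenumber (numeric header). The manifest has columns ``record_id``,
    ``subject_id``, ``replicate_index``, ``label`` and must cover every
    spectra row exactly once.
    """
    spec = _read_table(path)
    man = _read_table(manifest)
    if "record_id" not in spec.columns:
        raise SpectraFormatError(f"{path}: first column must be record_id")
    required = {"record_id", "subject_id", "replicate_index", "label"}
    missing = required - set(man.columns)
    if missing:
        raise SpectraFormatError(f"{manifest}: missing columns {sorted(missing)}")

    wn_cols = [c for c in spec.columns if c != "record_id"]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header: {exc}") from exc

    values = spec[wn_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SpectraFormatError(
            f"non-numeric/missing cell at record {spec['record_id'].iloc[r]!r}, "
            f"wavenumber {wn_cols[c]}"
        )

    man_idx = man.set_index("record_id")
    absent = set(man_idx.index) - set(spec["record_id"])
    if absent:
        raise SpectraFormatError(f"manifest references absent record ids: {sorted(absent)}")
    unmatched = set(spec["record_id"]) - set(man_idx.index)
    if unmatched:
        raise SpectraFormatError(f"spectra records missing from manifest: {sorted(unmatched)}")

    meta = man_idx.loc[spec["record_id"], ["subject_id", "replicate_index", "label"]]
    meta = meta.reset_index(drop=True)
    order = np.argsort(-wn, kind="stable")
    return SpectrumSet(wn[order], values[:, order], unit, meta)


def write_spectra(s: SpectrumSet, path: str | Path, manifest: str | Path) -> None:
    """Write a SpectrumSet as the delimited pair `read_spectra` accepts."""
    path, manifest = Path(path), Path(manifest)
    rec_ids = [
        f"{sub}_r{rep}"
        for sub, rep in zip(s.meta["subject_id"], s.meta["replicate_index"])
    ]
    spec = pd.DataFrame(s.values, columns=[f"{w:g}" for w in s.wavenumbers])
    spec.insert(0, "record_id", rec_ids)
    man = pd.DataFrame(
        {
            "record_id": rec_ids,
            "subject_id": s.meta["subject_id"].to_numpy(),
            "replicate_index": s.meta["replicate_index"].to_numpy(),
            "label": s.meta["label"].to_numpy(),
        }
    )
    sep_s = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    sep_m = "\t" if manifest.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    spec.to_csv(path, sep=sep_s, index=False, float_format="%.10g")
    man.to_csv(manifest, sep=sep_m, index=False)


def reflectance_to_absorbance(s: SpectrumSet) -> SpectrumSet:
    """Convert transflectance intensities to absorbance, A = log10(1/R)."""
    if s.unit != "reflectance":
        raise ValueError("input is not in reflectance units")
    if s.values.size and np.nanmin(s.values) <= 0:
        rows = np.unique(np.argwhere(s.values <= 0)[:, 0])
        ids = s.meta["subject_id"].iloc[rows].tolist()
        raise ValueError(f"non-positive reflectance for records of subjects {ids}")
    return replace(s, values=-np.log10(s.values), unit="absorbance")


def average_replicates(s: SpectrumSet, expected: int = 5) -> SpectrumSet:
    """Collapse instrumental replicates to one mean spectrum per subject.

    Emits a warning for subjects whose replicate count differs from
    `expected` (the acquisition protocol records five per sample).
    """
    groups = s.meta.groupby("subject_id", sort=False)
    rows, meta_rows = [], []
    for subject, idx in groups.indices.items():
        n_rep = len(idx)
        if n_rep != expected:
            warnings.warn(
                f"subject {subject!r} has {n_rep} replicates (expected {expected})",
                stacklevel=2,
            )
        rows.append(s.values[idx].mean(axis=0))
        meta_rows.append(
            {
                "subject_id": subject,
                "replicate_index": 0,
                "label": int(s.meta["label"].iloc[idx[0]]),
                "n_replicates": n_rep,
            }
        )
    return SpectrumSet(
        s.wavenumbers, np.asarray(rows), s.unit, pd.DataFrame(meta_rows)
    )


def extract_range(s: SpectrumSet, r: RangeName | str) -> SpectrumSet:
    """Keep the columns inside the closed interval of a named range."""
    r = RangeName(r)
    high, low = RANGE_BOUNDS[r]
    if s.wavenumbers.max() < high or s.wavenumbers.min() > low:
        raise ValueError(
            f"axis span {s.wavenumbers.max():g}-{s.wavenumbers.min():g} cm^-1 "
            f"does not cover {r.value} ({high:g}-{low:g})"
        )
    mask = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    return replace(s, wavenumbers=s.wavenumbers[mask], values=s.values[:, mask])
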