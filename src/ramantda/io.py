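"""Reading, writing and relabelling of Raman spectra and patient cohorts.

A :class:`RamanSpectrum` pairs a strictly increasing wavenumber axis
(cm^-1) with arbitrary-unit intensities and carries the patient identity
and the 4-class tumour grade label (EC = 0, CS G1 = 1, CS G2 = 2,
CS G3 = 3).  A :class:`SpectraDataset` groups spectra by patient; every
spectrum of one patient must share one label, which is what makes
patient-aware validation schemes well defined.

Spectrum files are two-column delimited text (wavenumber, intensity);
cohorts are described by a CSV manifest with columns
``patient_id,label,path``, one row per spectrum.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SpectraDataset",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "read_dataset",
    "write_dataset",
    "restrict_range",
    "relabel",
    "RELABEL_SCHEMES",
]

#: Default wavenumber window (cm^-1) used throughout the pipeline.
DEFAULT_WAVENUMBER_RANGE = (400.0, 1800.0)

VALID_LABELS = frozenset({0, 1, 2, 3})


class SpectrumParseError(ValueError):
    """A spectrum file contained a malformed row."""


@dataclass(frozen=True)
class RamanSpectrum:
    """One Raman spectrum with patient/label metadata.

    Parameters
    ----------
    wavenumbers
        Strictly increasing Raman shifts in cm^-1.
    intensities
        Scattered intensities (arbitrary units), same length, all finite.
    patient_id
        Opaque patient identifier.
    label
        Integer grade in {0, 1, 2, 3}, or ``None`` when unknown.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.shape != it.shape:
            raise ValueError("wavenumbers and intensities must be 1-D arrays of equal length")
        if wn.size < 2:
            raise ValueError(f"degenerate spectrum: need at least 2 points, got {wn.size}")
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(it)):
            raise ValueError("spectrum contains non-finite values")
        diffs = np.diff(wn)
        if np.any(diffs == 0):
            raise ValueError("duplicate wavenumbers in spectrum")
        if np.any(diffs < 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"label must be in {sorted(VALID_LABELS)}, got {self.label}")
        wn.setflags(write=False)
        it.setflags(write=False)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with intensities replaced."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectraDataset:
    """An ordered cohort of spectra grouped by patient."""

    spectra: list[RamanSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_label: dict[str, int | None] = {}
        for s in self.spectra:
            if s.patient_id in seen_label:
                if seen_label[s.patient_id] != s.label:
                    raise ValueError(
                        f"patient {s.patient_id!r} has conflicting labels "
                        f"{seen_label[s.patient_id]} and {s.label}"
                    )
            else:
                seen_label[s.patient_id] = s.label

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> RamanSpectrum:
        return self.spectra[i]

    @property
    def patient_order(self) -> list[str]:
        """Distinct patient ids in order of first appearance."""
        order: list[str] = []
        seen = set()
        for s in self.spectra:
            if s.patient_id not in seen:
                seen.add(s.patient_id)
                order.append(s.patient_id)
        return order

    @property
    def labels(self) -> np.ndarray:
        """Per-spectrum integer labels (requires all labels present)."""
        labs = [s.label for s in self.spectra]
        if any(l is None for l in labs):
            raise ValueError("dataset contains unlabelled spectra")
        return np.asarray(labs, dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.spectra]

    def patient_indices(self, patient_id: str) -> np.ndarray:
        return np.flatnonzero(np.asarray([s.patient_id == patient_id for s in self.spectra]))

    def patient_label(self, patient_id: str) -> int | None:
        for s in self.spectra:
            if s.patient_id == patient_id:
                return s.label
        raise KeyError(patient_id)

    def subset(self, indices: Iterable[int]) -> "SpectraDataset":
        return SpectraDataset([self.spectra[i] for i in indices])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(sample: str) -> str | None:
    """Return ',', '\\t' or None (whitespace) for a text sample."""
    if "," in sample:
        return ","
    if "\t" in sample:
        return "\t"
    return None


def read_spectrum(
    path: str | os.PathLike,
    delimiter: str | None = "auto",
    patient_id: str = "",
    label: int | None = None,
) -> RamanSpectrum:
    """Read a two-column (wavenumber, intensity) text file.

    Rows may appear in any wavenumber order; the result is sorted
    ascending.  Duplicate wavenumbers and non-numeric cells are rejected
    with the offending line number.
    """
    with open(path, "r") as fh:
        lines = fh.readlines()
    if delimiter == "auto":
        delimiter = _sniff_delimiter("".join(lines[:5]))
    wn: list[float] = []
    it: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split(delimiter) if delimiter else line.split()
        cells = [c for c in cells if c != ""]
        if len(cells) < 2:
            raise SpectrumParseError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
        try:
            x, y = float(cells[0]), float(cells[1])
        except ValueError as exc:
            raise SpectrumParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
        wn.append(x)
        it.append(y)
    if len(wn) < 2:
        raise ValueError(f"{path}: degenerate spectrum with {len(wn)} points")
    order = np.argsort(np.asarray(wn), kind="stable")
    wn_a = np.asarray(wn)[order]
    it_a = np.asarray(it)[order]
    if np.any(np.diff(wn_a) == 0):
        raise ValueError(f"{path}: duplicate wavenumbers")
    return RamanSpectrum(wn_a, it_a, patient_id=patient_id, label=label)


def write_spectrum(spectrum: RamanSpectrum, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text (full float precision)."""
    with open(path, "w") as fh:
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(x)!r}{delimiter}{float(y)!r}\n")


def read_dataset(manifest_path: str | os.PathLike, delimiter: str | None = "auto") -> SpectraDataset:
    """Read a cohort from a CSV manifest with columns patient_id,label,path.

    Relative spectrum paths are resolved against the manifest's directory.
    Manifest row order is preserved, which fixes the patient order.
    """
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "label", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{manifest_path}: empty manifest")
    base = os.path.dirname(os.fspath(manifest_path))
    spectra = []
    for row in df.itertuples(index=False):
        p = os.fspath(row.path)
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        spectra.append(
            read_spectrum(p, delimiter=delimiter, patient_id=str(row.patient_id), label=int(row.label))
        )
    return SpectraDataset(spectra)


def write_dataset(dataset: SpectraDataset, out_dir: str | os.PathLike, delimiter: str = ",") -> str:
    """Write every spectrum plus a ``manifest.csv``; returns the manifest path."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "path"])
        for i, s in enumerate(dataset):
            fname = f"spectrum_{i:05d}.csv"
            write_spectrum(s, os.path.join(out_dir, fname), delimiter=delimiter)
            writer.writerow([s.patient_id, s.label, fname])
    return manifest


# ---------------------------------------------------------------------------
# Range restriction and label remapping
# ---------------------------------------------------------------------------

def restrict_range(
    spectrum: RamanSpectrum,
    lo: float = DEFAULT_WAVENUMBER_RANGE[0],
    hi: float = DEFAULT_WAVENUMBER_RANGE[1],
) -> RamanSpectrum:
    """Keep exactly the samples with lo <= wavenumber <= hi (closed interval).

    The default window 400-1800 cm^-1 covers the fingerprint region where
    the biologically informative Raman bands live.  Idempotent.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 2:
        raise ValueError(f"restriction to [{lo}, {hi}] leaves {int(mask.sum())} points (< 2)")
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers[mask],
        intensities=spectrum.intensities[mask],
    )


#: scheme name -> mapping of the 4 grade codes.
RELABEL_SCHEMES: dict[str, dict[int, int]] = {
    # identity: the full 4-grade task
    "four": {0: 0, 1: 1, 2: 2, 3: 3},
    # EC vs CS G1 vs {CS G2, CS G3}
    "three": {0: 0, 1: 1, 2: 2, 3: 2},
    # benign vs malignant: EC vs any CS grade
    "binary_ec_vs_cs": {0: 0, 1: 1, 2: 1, 3: 1},
    # low/no malignancy vs high malignancy: {EC, CS G1} vs {CS G2, CS G3}
    "binary_low_vs_high": {0: 0, 1: 0, 2: 1, 3: 1},
}


def relabel(labels: Sequence[int] | np.ndarray, scheme: str) -> np.ndarray:
    """Remap 4-class grade labels onto a coarser classification task.

    ``four`` is the identity, ``three`` merges the two high grades,
    ``binary_ec_vs_cs`` separates benign from malignant, and
    ``binary_low_vs_high`` splits low from high malignancy.
    """
    if scheme not in RELABEL_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(RELABEL_SCHEMES)}")
    mapping = RELABEL_SCHEMES[scheme]
    labs = np.asarray(labels, dtype=int)
    bad = set(np.unique(labs)) - VALID_LABELS
    if bad:
        raise ValueError(f"labels outside {{0,1,2,3}}: {sorted(bad)}")
    lut = np.array([mapping[i] for i in range(4)], dtype=int)
    return lut[labs]
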