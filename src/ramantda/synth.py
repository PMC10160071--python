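"""Synthetic Raman-like cohorts with class structure and patient effects.

The generator emulates baseline-corrected tissue Raman spectra in the
fingerprint region: each tumour class is a :class:`ClassProfile` — a sum
of Lorentzian (optionally Gaussian) lines on a low-order polynomial
baseline — and the four default profiles share most bands while showing
graded amplitude trends (collagen-associated bands 856/937 cm^-1
decreasing, phenylalanine 1003 cm^-1 and nucleic-acid 1090 cm^-1
increasing with malignancy), so adjacent grades look similar, as in real
cohorts.

Patient identity enters as a multiplicative per-peak amplitude jitter, a
global intensity scale and a small band-position offset, all drawn once
per patient; per-spectrum variation is additive Gaussian noise.  Because
the patient effect is comparable to the between-class contrast while the
per-spectrum noise is small, spectra of one patient cluster tightly —
patient-naive cross-validation looks optimistic and leave-one-patient-out
becomes the honest scheme, which is the behaviour the downstream pipeline
tests exercise.

Everything is a pure function of (spec, profiles, grid, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import RamanSpectrum, SpectraDataset

__all__ = [
    "ClassProfile",
    "CohortSpec",
    "default_profiles",
    "separable_profiles",
    "generate_cohort",
    "cohort_from_config",
    "separable_cohort",
    "study_cohort",
    "holdout_cohort",
    "DEFAULT_GRID",
    "STUDY_PATIENT_COUNTS",
    "STUDY_PATIENT_LABELS",
    "HOLDOUT_PATIENT_LABELS",
]

#: Default generation grid: fingerprint region sampled every 14 cm^-1,
#: enough to resolve the >= 25 cm^-1-wide tissue bands the profiles use.
DEFAULT_GRID = np.arange(400.0, 1800.0 + 14.0, 14.0)
DEFAULT_GRID.setflags(write=False)

#: Per-patient spectrum counts of the 400-spectrum training cohort design.
STUDY_PATIENT_COUNTS = (32, 31, 37, 24, 38, 38, 50, 50, 49, 51)
#: Grade label of each training-cohort patient (EC=0 ... CS G3=3).
STUDY_PATIENT_LABELS = (0, 0, 0, 1, 1, 1, 2, 2, 3, 3)
#: Grade labels of the 10-patient, one-spectrum-each held-out cohort.
HOLDOUT_PATIENT_LABELS = (1, 2, 2, 1, 1, 2, 0, 3, 3, 0)


@dataclass(frozen=True)
class ClassProfile:
    """Closed-form mean spectrum of one tumour class.

    ``peak_widths`` are FWHM in cm^-1; amplitudes are peak heights in
    arbitrary units.  ``baseline_coefficients`` are polynomial
    coefficients in the normalized coordinate u = (w - 400)/1400,
    lowest order first.
    """

    peak_centers: tuple[float, ...]
    peak_amplitudes: tuple[float, ...]
    peak_widths: tuple[float, ...]
    baseline_coefficients: tuple[float, ...] = (0.0,)
    noise_std: float = 4.0
    line_shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not (len(self.peak_centers) == len(self.peak_amplitudes) == len(self.peak_widths)):
            raise ValueError("peak_centers/amplitudes/widths must have equal length")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak widths must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.line_shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown line_shape {self.line_shape!r}")

    def evaluate(
        self,
        grid: np.ndarray,
        amplitudes: Sequence[float] | None = None,
        centers: Sequence[float] | None = None,
    ) -> np.ndarray:
        """Noise-free profile on ``grid``; amplitudes/centers may be overridden."""
        w = np.asarray(grid, dtype=float)
        amps = np.asarray(self.peak_amplitudes if amplitudes is None else amplitudes)
        cens = np.asarray(self.peak_centers if centers is None else centers)
        y = np.zeros_like(w)
        for a, c, fwhm in zip(amps, cens, self.peak_widths):
            if self.line_shape == "lorentzian":
                g = fwhm / 2.0  # half width at half maximum
                y += a * g * g / ((w - c) ** 2 + g * g)
            else:
                s = fwhm / 2.3548200450309493  # FWHM -> sigma
                y += a * np.exp(-0.5 * ((w - c) / s) ** 2)
        u = (w - 400.0) / 1400.0
        y += np.polynomial.polynomial.polyval(u, np.asarray(self.baseline_coefficients))
        return y


@dataclass(frozen=True)
class CohortSpec:
    """Composition and variability of one synthetic patient cohort."""

    per_patient_counts: tuple[int, ...]
    patient_labels: tuple[int, ...]
    patient_effect_std: float = 0.12
    patient_shift_std: float = 1.5
    seed: int = 0
    patient_id_prefix: str = "P"

    def __post_init__(self) -> None:
        if len(self.per_patient_counts) != len(self.patient_labels):
            raise ValueError("per_patient_counts and patient_labels must have equal length")
        if any(c <= 0 for c in self.per_patient_counts):
            raise ValueError("per-patient counts must be positive")
        if any(l not in (0, 1, 2, 3) for l in self.patient_labels):
            raise ValueError("patient labels must lie in {0,1,2,3}")
        if self.patient_effect_std < 0 or self.patient_shift_std < 0:
            raise ValueError("effect scales must be >= 0")


# Shared band set: centers, FWHM, and per-class peak heights (a.u.).
# Amplitude trends are monotone in grade so adjacent grades differ least.
_BAND_CENTERS = (856.0, 937.0, 1003.0, 1090.0, 1245.0, 1302.0, 1450.0, 1660.0)
_BAND_WIDTHS = (26.0, 26.0, 25.0, 28.0, 34.0, 30.0, 32.0, 36.0)
_BAND_AMPLITUDES = {
    0: (320.0, 260.0, 150.0, 80.0, 140.0, 150.0, 260.0, 300.0),
    1: (260.0, 210.0, 190.0, 110.0, 160.0, 160.0, 250.0, 290.0),
    2: (200.0, 160.0, 230.0, 150.0, 185.0, 170.0, 245.0, 275.0),
    3: (150.0, 120.0, 270.0, 190.0, 210.0, 180.0, 240.0, 260.0),
}
_BASELINE = (30.0, 20.0, -15.0)


def default_profiles(noise_std: float = 4.0, line_shape: str = "lorentzian") -> dict[int, ClassProfile]:
    """The four default class profiles (EC=0 ... CS G3=3)."""
    return {
        lab: ClassProfile(
            peak_centers=_BAND_CENTERS,
            peak_amplitudes=_BAND_AMPLITUDES[lab],
            peak_widths=_BAND_WIDTHS,
            baseline_coefficients=_BASELINE,
            noise_std=noise_std,
            line_shape=line_shape,
        )
        for lab in (0, 1, 2, 3)
    }


def separable_profiles(contrast: float = 2.0, noise_std: float = 4.0) -> dict[int, ClassProfile]:
    """Profiles with class deviations from the grand mean scaled by ``contrast``.

    Used for well-separated benchmark cohorts where the classification
    signal should dominate patient identity.
    """
    mean = np.mean([_BAND_AMPLITUDES[l] for l in range(4)], axis=0)
    out = {}
    for lab, prof in default_profiles(noise_std=noise_std).items():
        amps = mean + contrast * (np.asarray(prof.peak_amplitudes) - mean)
        amps = np.maximum(amps, 10.0)
        out[lab] = replace(prof, peak_amplitudes=tuple(float(a) for a in amps))
    return out


def generate_cohort(
    spec: CohortSpec,
    profiles: Mapping[int, ClassProfile] | None = None,
    grid: np.ndarray | None = None,
) -> SpectraDataset:
    """Generate a patient cohort of class-structured synthetic spectra.

    Per patient, drawn once: a multiplicative per-peak amplitude jitter
    of relative scale ``patient_effect_std``, a global intensity scale of
    half that relative scale, and a per-peak center offset of std
    ``patient_shift_std`` cm^-1.  Per spectrum: i.i.d. additive Gaussian
    noise of the class profile's ``noise_std``.
    """
    profiles = default_profiles() if profiles is None else profiles
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    missing = sorted(set(spec.patient_labels) - set(profiles))
    if missing:
        raise ValueError(f"no class profile for labels {missing}")
    spectra: list[RamanSpectrum] = []
    width = max(2, len(str(len(spec.per_patient_counts))))
    for p, (count, label) in enumerate(zip(spec.per_patient_counts, spec.patient_labels)):
        prof = profiles[label]
        rng_p = np.random.default_rng(np.random.SeedSequence((spec.seed, 7919, p)))
        n_peaks = len(prof.peak_centers)
        amp_jitter = 1.0 + spec.patient_effect_std * rng_p.standard_normal(n_peaks)
        amp_jitter = np.maximum(amp_jitter, 0.2)
        scale = max(0.2, 1.0 + 0.5 * spec.patient_effect_std * rng_p.standard_normal())
        centers = np.asarray(prof.peak_centers) + spec.patient_shift_std * rng_p.standard_normal(n_peaks)
        base = scale * prof.evaluate(
            grid,
            amplitudes=np.asarray(prof.peak_amplitudes) * amp_jitter,
            centers=centers,
        )
        pid = f"{spec.patient_id_prefix}{p + 1:0{width}d}"
        for s in range(count):
            rng_s = np.random.default_rng(np.random.SeedSequence((spec.seed, 104729, p, s)))
            noise = prof.noise_std * rng_s.standard_normal(grid.size) if prof.noise_std > 0 else 0.0
            spectra.append(RamanSpectrum(grid.copy(), base + noise, patient_id=pid, label=label))
    return SpectraDataset(spectra)


def cohort_from_config(config: Mapping) -> SpectraDataset:
    """Build a cohort from a plain mapping (e.g. parsed YAML/TOML).

    Expected keys: ``cohort`` (CohortSpec fields), ``profiles`` (label ->
    ClassProfile fields) and optionally ``grid`` with ``lo``/``hi``/``step``
    in cm^-1.
    """
    spec = CohortSpec(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in dict(config["cohort"]).items()})
    profiles = {
        int(lab): ClassProfile(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in dict(fields).items()})
        for lab, fields in dict(config["profiles"]).items()
    }
    grid = None
    if "grid" in config:
        g = config["grid"]
        grid = np.arange(float(g["lo"]), float(g["hi"]) + float(g["step"]), float(g["step"]))
    return generate_cohort(spec, profiles=profiles, grid=grid)


def separable_cohort(seed: int, contrast: float = 3.0,
                     patient_effect_std: float = 0.05,
                     grid: np.ndarray | None = None) -> SpectraDataset:
    """A well-separated benchmark cohort on the study composition.

    Class amplitude deviations are scaled by ``contrast`` and the patient
    effect is kept well below the between-class contrast, so the class
    signal dominates patient identity — the regime in which a
    patient-aware classifier should recover the labels.
    """
    return study_cohort(seed, patient_effect_std=patient_effect_std,
                        profiles=separable_profiles(contrast), grid=grid)


def study_cohort(seed: int, patient_effect_std: float = 0.12,
                 profiles: Mapping[int, ClassProfile] | None = None,
                 grid: np.ndarray | None = None) -> SpectraDataset:
    """The 400-spectrum, 10-patient training cohort design.

    Patient spectrum counts (32, 31, 37, 24, 38, 38, 50, 50, 49, 51) and
    grade labels (0, 0, 0, 1, 1, 1, 2, 2, 3, 3), on the default
    400-1800 cm^-1 grid.
    """
    spec = CohortSpec(
        per_patient_counts=STUDY_PATIENT_COUNTS,
        patient_labels=STUDY_PATIENT_LABELS,
        patient_effect_std=patient_effect_std,
        seed=seed,
        patient_id_prefix="S",
    )
    return generate_cohort(spec, profiles=profiles, grid=grid)


def holdout_cohort(seed: int, patient_effect_std: float = 0.12,
                   profiles: Mapping[int, ClassProfile] | None = None,
                   grid: np.ndarray | None = None) -> SpectraDataset:
    """Ten new patients, one spectrum each, grades (1,2,2,1,1,2,0,3,3,0).

    Patient ids are disjoint from :func:`study_cohort`; a different seed
    stream stands in for the different acquisition session.
    """
    spec = CohortSpec(
        per_patient_counts=(1,) * 10,
        patient_labels=HOLDOUT_PATIENT_LABELS,
        patient_effect_std=patient_effect_std,
        seed=seed + 1_000_003,
        patient_id_prefix="H",
    )
    return generate_cohort(spec, profiles=profiles, grid=grid)
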