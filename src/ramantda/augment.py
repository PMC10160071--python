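"""Six-fold spectral data augmentation.

Each original spectrum is kept and joined by five variants that emulate
measurement nuisances:

1. additive Gaussian noise, std = max(spectrum)/1000;
2. additive Gaussian noise, std = 1;
3. wavenumber shift drawn uniformly from [-5, 5] cm^-1;
4. small noise (1) plus a shift (3);
5. unit noise (2) plus a shift (3).

The shift models calibration inaccuracy: intensities are resampled at
(wavenumber - delta) by linear interpolation back onto the original
grid, with boundary intensities extending beyond the support.  One RNG
stream is derived per (spectrum, variant), so augmentation is
reproducible and independent of processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RamanSpectrum, SpectraDataset

__all__ = [
    "AugmentationConfig",
    "add_gaussian_noise",
    "shift_spectrum",
    "augment_sixfold",
    "VARIANT_NAMES",
]

VARIANT_NAMES = (
    "original",
    "noise_small",
    "noise_unit",
    "shift",
    "noise_small_shift",
    "noise_unit_shift",
)


@dataclass(frozen=True)
class AugmentationConfig:
    """Scales of the augmentation transforms.

    ``noise_small_divisor``: the small-noise std is the spectrum's
    maximum intensity divided by this.  ``noise_unit_std``: std of the
    second noise level (intensity units).  ``shift_halfwidth``: shifts
    are drawn uniformly from [-shift_halfwidth, +shift_halfwidth] cm^-1.
    """

    noise_small_divisor: float = 1000.0
    noise_unit_std: float = 1.0
    shift_halfwidth: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_small_divisor <= 0:
            raise ValueError("noise_small_divisor must be > 0")
        if self.noise_unit_std < 0 or self.shift_halfwidth < 0:
            raise ValueError("noise and shift scales must be >= 0")


def add_gaussian_noise(spectrum: RamanSpectrum, std: float, rng: np.random.Generator) -> RamanSpectrum:
    """Add i.i.d. N(0, std^2) to the intensities; wavenumbers unchanged."""
    if std < 0:
        raise ValueError("std must be >= 0")
    if std == 0:
        return spectrum
    return spectrum.with_intensities(spectrum.intensities + std * rng.standard_normal(len(spectrum)))


def shift_spectrum(
    spectrum: RamanSpectrum,
    delta: float | None = None,
    rng: np.random.Generator | None = None,
    halfwidth: float = 5.0,
) -> RamanSpectrum:
    """Shift the spectrum by ``delta`` cm^-1 along the wavenumber axis.

    When ``delta`` is None it is sampled uniformly from
    [-halfwidth, +halfwidth] using ``rng``.  The shifted signal is
    evaluated on the original grid by linear interpolation; positions
    outside the original support take the boundary intensity.
    """
    if delta is None:
        if rng is None:
            raise ValueError("need an rng to sample delta")
        delta = float(rng.uniform(-halfwidth, halfwidth))
    if delta == 0:
        return spectrum
    shifted = np.interp(
        spectrum.wavenumbers - delta, spectrum.wavenumbers, spectrum.intensities
    )
    return spectrum.with_intensities(shifted)


def _variant_rng(seed: int, spectrum_index: int, variant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, 15485863, spectrum_index, variant)))


def _make_variant(s: RamanSpectrum, variant: int, idx: int, cfg: AugmentationConfig) -> RamanSpectrum:
    rng = _variant_rng(cfg.seed, idx, variant)
    small_std = float(np.max(s.intensities)) / cfg.noise_small_divisor
    if variant == 1:
        return add_gaussian_noise(s, small_std, rng)
    if variant == 2:
        return add_gaussian_noise(s, cfg.noise_unit_std, rng)
    if variant == 3:
        return shift_spectrum(s, rng=rng, halfwidth=cfg.shift_halfwidth)
    if variant == 4:
        return add_gaussian_noise(shift_spectrum(s, rng=rng, halfwidth=cfg.shift_halfwidth), small_std, rng)
    if variant == 5:
        return add_gaussian_noise(shift_spectrum(s, rng=rng, halfwidth=cfg.shift_halfwidth), cfg.noise_unit_std, rng)
    raise ValueError(f"unknown variant {variant}")


def augment_sixfold(dataset: SpectraDataset, config: AugmentationConfig | None = None) -> SpectraDataset:
    """Expand a dataset six-fold: each original plus its five variants.

    Labels and patient ids are inherited, so per-patient, per-label
    counts multiply by exactly six.  Fully reproducible from
    ``config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    cfg = AugmentationConfig() if config is None else config
    out: list[RamanSpectrum] = []
    for idx, s in enumerate(dataset):
        out.append(s)
        for variant in range(1, 6):
            out.append(_make_variant(s, variant, idx, cfg))
    return SpectraDataset(out)
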