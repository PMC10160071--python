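import numpy as np
import pytest

from ramantda import (
    CohortSpec,
    PersistenceDiagram,
    RamanSpectrum,
    SpectraDataset,
    default_profiles,
    generate_cohort,
)

#: Coarse grid for pipeline-mechanics tests where persistence cost matters
#: more than spectral realism.
COARSE_GRID = np.arange(400.0, 1800.0 + 56.0, 56.0)  # 26 samples


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_spectrum():
    wn = np.arange(400.0, 420.0)
    return RamanSpectrum(wn, np.sin(wn / 3.0) + 2.0, patient_id="P1", label=0)


@pytest.fixture
def tiny_cohort():
    """3 patients x 4 spectra on a coarse grid; two classes."""
    spec = CohortSpec(
        per_patient_counts=(4, 4, 4),
        patient_labels=(0, 0, 1),
        patient_effect_std=0.05,
        seed=7,
    )
    return generate_cohort(spec, profiles=default_profiles(), grid=COARSE_GRID)


def random_cloud(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=(n, 2))


def toy_diagram(h0_deaths, h1=()) -> PersistenceDiagram:
    h0 = np.column_stack([np.zeros(len(h0_deaths)), np.asarray(h0_deaths, float)])
    return PersistenceDiagram(h0, np.asarray(h1, float).reshape(-1, 2))
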