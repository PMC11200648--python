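import numpy as np
import pandas as pd
import pytest

from gdmnir import (
    SpectrumSet,
    average_replicates,
    generate_spectra,
    reflectance_to_absorbance,
    second_trimester_config,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_set(values, wavenumbers=None, unit="absorbance", labels=None, subjects=None, reps=None):
    """Small-spectra helper used across test modules."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if wavenumbers is None:
        wavenumbers = np.linspace(10_500, 4000, p)
    meta = pd.DataFrame(
        {
            "subject_id": subjects if subjects is not None else [f"S{i}" for i in range(n)],
            "replicate_index": reps if reps is not None else [1] * n,
            "label": labels if labels is not None else [0] * n,
        }
    )
    return SpectrumSet(np.asarray(wavenumbers, float), values, unit, meta)


@pytest.fixture(scope="session")
def coarse_cohort():
    """Subject-level absorbance spectra on a coarse grid (fast unit tests)."""
    cfg = second_trimester_config(seed=11, grid_step=8.0)
    return reflectance_to_absorbance(average_replicates(generate_spectra(cfg)))
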