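import numpy as np
import pytest

from specgrade import default_study_design, generate_cohort, preprocess
from specgrade.core import SpectralDataset


def make_dataset(
    intensities,
    wavenumbers=None,
    labels=None,
    patients=None,
    stage_tag="raw",
):
    """Small handmade dataset; defaults: descending integer axis, one patient
    per spectrum, all G1."""
    X = np.atleast_2d(np.asarray(intensities, dtype=float))
    n, p = X.shape
    if wavenumbers is None:
        wavenumbers = np.arange(p, 0, -1, dtype=float) * 4.0 + 896.0
    if labels is None:
        labels = ["G1"] * n
    if patients is None:
        patients = [f"P{i:03d}" for i in range(n)]
    return SpectralDataset(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        intensities=X,
        spectrum_ids=np.array([f"s{i:03d}" for i in range(n)], dtype=object),
        patient_ids=np.array(patients, dtype=object),
        labels=np.array(labels, dtype=object),
        stage_tag=stage_tag,
    )


@pytest.fixture(scope="session")
def study_design():
    return default_study_design()


@pytest.fixture(scope="session")
def cohort(study_design):
    design, bands, effects = study_design
    return generate_cohort(design, bands, effects, seed=1)


@pytest.fixture(scope="session")
def preprocessed(cohort):
    return preprocess(cohort)
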