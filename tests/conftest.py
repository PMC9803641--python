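import numpy as np
import pandas as pd
import pytest

from dcmmet.preprocess import preprocess_pipeline
from dcmmet.synthdata import SimConfig, simulate_cohort, simulate_followup
from dcmmet.types import MetaboMatrix

SMALL = dict(
    group_sizes=(12, 6, 6, 8),
    n_metabolites=80,
    block_sizes=(8, 8),
    n_disease_effects=12,
    n_diet_effects=10,
    n_overlap_effects=6,
    effect_size=2.0,
    survivor_fraction=0.5,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_followup(small_cohort, small_config):
    samples, matrix, truth = small_cohort
    return simulate_followup(samples, matrix, truth, small_config)


@pytest.fixture(scope="session")
def small_log(small_cohort):
    samples, matrix, _ = small_cohort
    mlog, report = preprocess_pipeline(matrix, samples)
    return samples, mlog, report


def toy_matrix(values, metabolites=None, samples=None, log_scale=True):
    """Small MetaboMatrix from a plain array, with stub annotations."""
    values = np.asarray(values, dtype=float)
    mets = metabolites or [f"M{j + 1:04d}" for j in range(values.shape[1])]
    sids = samples or [f"dog{i:03d}" for i in range(values.shape[0])]
    annotation = pd.DataFrame(
        {"super_pathway": "Amino acid", "sub_pathway": "toy"},
        index=pd.Index(mets, name="metabolite_id"),
    )
    return MetaboMatrix(
        pd.DataFrame(values, index=pd.Index(sids, name="sample_id"), columns=mets),
        annotation,
        log_scale=log_scale,
    )


def toy_samples(n, disease=None, diet=None, batch=None, ctni=None):
    sids = [f"dog{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": sids,
            "dog_id": sids,
            "disease": disease if disease is not None else ["DCM"] * (n // 2) + ["control"] * (n - n // 2),
            "diet": diet if diet is not None else ["NT"] * (n // 2) + ["T"] * (n - n // 2),
            "age": np.linspace(2, 12, n),
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "body_weight": 30.0,
            "batch": batch if batch is not None else "B1",
            "timepoint": "baseline",
            "ctni": ctni if ctni is not None else np.linspace(0.5, 2.0, n),
        }
    )
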