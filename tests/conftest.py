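import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("kinsurv", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("kinsurv")


@pytest.fixture()
def six_record_cox():
    """Tiny survival fixture with distinct event times and one binary covariate."""
    return pd.DataFrame(
        {
            "observed_age": [41.0, 43.0, 46.0, 50.0, 52.0, 55.0],
            "event": [1, 0, 1, 1, 0, 1],
            "covariate_1": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )


def _parent_rows(subject, father_age, father_event, mother_age, mother_event, cov=0.0, adopted=False):
    return [
        {
            "subject_id": subject,
            "parent_sex": "father",
            "observed_age": father_age,
            "event": father_event,
            "adopted": adopted,
            "age_valid": father_age <= 115,
            "covariate_1": cov,
        },
        {
            "subject_id": subject,
            "parent_sex": "mother",
            "observed_age": mother_age,
            "event": mother_event,
            "adopted": adopted,
            "age_valid": mother_age <= 115,
            "covariate_1": cov,
        },
    ]


@pytest.fixture()
def toy_qc_table():
    """Ten subjects: one adopted, one invalid parent age, one missing
    covariate, one father dead at 38 (mother usable), six clean."""
    rows = []
    rows += _parent_rows("S01", 72, 1, 80, 0, adopted=True)
    rows += _parent_rows("S02", 120, 1, 78, 1)
    rows += _parent_rows("S03", 70, 1, 75, 0, cov=np.nan)
    rows += _parent_rows("S04", 38, 1, 81, 0)
    for i in range(5, 11):
        rows += _parent_rows(f"S{i:02d}", 60 + i, 1, 65 + i, i % 2)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    from kinsurv import SimConfig, constant_effects, generate_cohort

    config = SimConfig(
        n_subjects=4000,
        n_variants=3,
        allele_freqs=np.array([0.3, 0.5, 0.1]),
        causal_effects=constant_effects([0.2, 0.0, 0.0]),
        seed=42,
    )
    pheno, geno, truth = generate_cohort(config)
    return config, pheno, geno, truth
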