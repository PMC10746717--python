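import numpy as np
import pandas as pd
import pytest

from tearomics import models, preprocess, simulate
from tearomics.containers import ClinicalTable, ProteinQuantTable


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient, 80-protein cohort with 5 planted severity effects."""
    cfg = simulate.SimConfig(
        counts_per_level={2: 15, 3: 25, 4: 20},
        n_proteins=80,
        planted_effects=[
            simulate.PlantedEffect(i, {3: 0.6 * (-1) ** i, 4: 1.2 * (-1) ** i})
            for i in range(5)
        ],
        seed=11,
    )
    quant, clinical = simulate.generate_cohort(cfg)
    return cfg, quant, clinical


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    _, quant, clinical = small_cohort
    clinical2, matrix, report = preprocess.preprocess_pipeline(clinical, quant)
    return clinical2, matrix, report


@pytest.fixture(scope="session")
def multiclass_model(preprocessed_cohort):
    clinical, matrix, _ = preprocessed_cohort
    task = models.TaskSpec(kind="multiclass", seed=7)
    model = models.train_classifier(matrix, clinical.levels, task)
    return model, matrix, clinical


def make_quant(values, names=None, sample_prefix="S"):
    """Build a ProteinQuantTable from a plain 2D list/array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    accs = [f"P{j:05d}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"{sample_prefix}{i}" for i in range(arr.shape[0])],
                      columns=accs)
    name_map = pd.Series(names if names is not None else accs, index=accs)
    return ProteinQuantTable(df, name_map)


def make_clinical(levels, sample_prefix="S"):
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"{sample_prefix}{i}" for i in range(len(levels))],
        "mgd_level": list(levels),
    }))
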