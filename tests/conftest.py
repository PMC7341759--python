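import numpy as np
import pandas as pd
import pytest

from lncnet import ExpressionMatrix, ModuleSpec, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired cohort with one planted oncogenic, grade-linked module.

    12 patients and low noise give the planted 1.5-log2 tumor shift enough
    power to survive the FDR + fold-change gates at this scale.
    """
    cfg = SimConfig(
        n_patients=12,
        n_lnc=30,
        n_mrna=40,
        feature_noise_sd=0.2,
        modules=[
            ModuleSpec(
                n_lnc_members=3,
                n_mrna_members=5,
                target_r=0.95,
                tumor_shift=1.5,
                linked_group="grade",
                phenotype_effect=1.0,
            )
        ],
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def small_matrix():
    """3x4 expression matrix with a paired 2-patient design."""
    values = pd.DataFrame(
        np.array(
            [
                [8.0, 6.5, 7.2, 7.0],
                [10.1, 9.9, 10.4, 10.2],
                [5.5, 5.0, 6.1, 5.9],
            ]
        ),
        index=["F1", "F2", "F3"],
        columns=["P1_T", "P1_NT", "P2_T", "P2_NT"],
    )
    design = pd.DataFrame(
        {
            "sample_id": ["P1_T", "P1_NT", "P2_T", "P2_NT"],
            "patient_id": ["P1", "P1", "P2", "P2"],
            "tissue": ["T", "NT", "T", "NT"],
        }
    )
    return ExpressionMatrix(values), design
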