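import numpy as np
import pandas as pd
import pytest

from pairomics import (
    ExpressionMatrix,
    OmicsKind,
    SampleDesign,
    SimulationConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down deregulated cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=7, n_mirna=40, n_gene=250, n_protein=90)
    return generate_cohort(cfg)


@pytest.fixture()
def paired_design():
    def make(n_pairs: int) -> SampleDesign:
        patients = [f"P{i:02d}" for i in range(1, n_pairs + 1)]
        return SampleDesign(
            pd.DataFrame(
                {
                    "sample_id": [f"{p}_T" for p in patients]
                    + [f"{p}_C" for p in patients],
                    "patient_id": patients * 2,
                    "condition": ["tumor"] * n_pairs + ["control"] * n_pairs,
                }
            )
        )

    return make


@pytest.fixture()
def matrix_from_arrays(paired_design):
    """Build an ExpressionMatrix + design from explicit tumor/control grids."""

    def make(tumor: np.ndarray, control: np.ndarray, kind=OmicsKind.MRNA):
        tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
        control = np.atleast_2d(np.asarray(control, dtype=float))
        n_feat, n_pairs = tumor.shape
        design = paired_design(n_pairs)
        df = pd.DataFrame(
            np.hstack([tumor, control]),
            index=[f"f{i}" for i in range(n_feat)],
            columns=design.samples_of("tumor") + design.samples_of("control"),
        )
        return ExpressionMatrix(df, kind), design

    return make
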