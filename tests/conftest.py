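import numpy as np
import pytest

from nmrfp import CohortSpec, assemble_matrix, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (65/29/75), shared across the suite."""
    return generate_cohort(CohortSpec(seed=8))


@pytest.fixture(scope="session")
def noesy_training(default_cohort):
    """NOESY binned matrix split into the training contrast and relapsed rows."""
    cohort = default_cohort
    matrix = assemble_matrix(cohort.spectra["NOESY"])
    groups = cohort.clinical.set_index("id")["group"]
    train_idx = [i for i, s in enumerate(matrix.sample_ids) if groups[s] != "eCRC_relapsed"]
    rel_idx = [i for i, s in enumerate(matrix.sample_ids) if groups[s] == "eCRC_relapsed"]
    ids = [matrix.sample_ids[i] for i in train_idx]
    y = np.array(
        ["metastatic" if groups[s] == "mCRC" else "early" for s in ids], dtype=object
    )
    return {
        "matrix": matrix,
        "X": matrix.values[train_idx],
        "y": y,
        "ids": ids,
        "X_rel": matrix.values[rel_idx],
        "rel_ids": [matrix.sample_ids[i] for i in rel_idx],
        "cohort": cohort,
    }


@pytest.fixture()
def small_spec():
    """Small, fast cohort spec for structural tests."""
    return CohortSpec(n_ecrc_free=10, n_ecrc_relapsed=4, n_mcrc=10, n_points=2048, seed=3)
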