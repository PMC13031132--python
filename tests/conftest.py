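import numpy as np
import pandas as pd
import pytest

from zonemap import IntensityMatrix, ProteomeSpec, TissueSpec, generate_proteome, generate_tissue


@pytest.fixture(scope="session")
def tissue_scene():
    """Default synthetic two-vein scene (channels, contours, true anchors)."""
    spec = TissueSpec(seed=0)
    channels, contours, anchors = generate_tissue(spec)
    return spec, channels, contours, anchors


@pytest.fixture(scope="session")
def small_cohort():
    """Small zonated cohort with ground truth (6 patients x 20 cells)."""
    spec = ProteomeSpec(
        n_patients=6, cells_per_patient=20, n_proteins=40,
        frac_zonated=0.5, seed=7,
    )
    matrix, truth = generate_proteome(spec)
    return spec, matrix, truth


def make_matrix(values: np.ndarray, S=None, patients=None, conditions=None) -> IntensityMatrix:
    """Assemble an IntensityMatrix from a raw proteins x samples array."""
    n_prot, n_samp = values.shape
    sample_ids = [f"s{j:03d}" for j in range(n_samp)]
    protein_ids = [f"prot{i:03d}" for i in range(n_prot)]
    if S is None:
        S = np.linspace(0, 1, n_samp)
    if patients is None:
        patients = ["P1"] * n_samp
    if conditions is None:
        conditions = ["healthy"] * n_samp
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "patient_id": patients,
         "condition": conditions, "S": S}
    ).set_index("sample_id")
    return IntensityMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        meta=meta,
    )
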