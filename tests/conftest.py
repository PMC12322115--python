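import numpy as np
import pandas as pd
import pytest

from evopharm.io import VariantTable
from evopharm.simulate import SimulationParams, generate_cohort


def make_variant_table(rows):
    """rows: (patient, sample, timepoint, gene, change, ref, alt)."""
    return VariantTable(pd.DataFrame(rows, columns=[
        "patient_id", "sample_id", "timepoint", "gene", "protein_change",
        "ref_count", "alt_count",
    ]))


@pytest.fixture(scope="session")
def planted_cohort():
    """30-patient cohort, 10 per planted evolution class, guaranteed presence."""
    classes = ("persistence",) * 10 + ("extinction",) * 10 + ("expansion",) * 10
    params = SimulationParams(
        n_patients=30, evolution_classes=classes, n_genes=60, n_drugs=8,
        n_signature_drugs=0,
    )
    return generate_cohort(params, seed=20240901)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
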