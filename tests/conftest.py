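import numpy as np
import pytest

from famlong.covariance import build_components
from famlong.igls import longitudinal_data_from_table
from famlong.pedigree import kinship_matrices, parse_ped
from famlong.simulate import Nuclear, SimConfig, simulate_dataset

TRIO_PED = """\
F1 1 0 0 1
F1 2 0 0 2
F1 3 1 2 1
"""

# two full-sib parents mated to produce an inbred child (plus grandparents)
INBRED_PED = """\
F1 gpa 0 0 1
F1 gma 0 0 2
F1 sibA gpa gma 1
F1 sibB gpa gma 2
F1 kid sibA sibB 1
"""


@pytest.fixture
def trio_ped():
    return parse_ped(TRIO_PED)


@pytest.fixture
def inbred_ped():
    return parse_ped(INBRED_PED)


def make_fit_inputs(simdata, covariates=(), snv=None, first_visit_only=False):
    """LongitudinalData (+ optional dosage column) and matching design."""
    table = simdata.phenotypes
    if first_visit_only:
        table = table[table["visit"] == table["visit"].min()]
    data = longitudinal_data_from_table(table, simdata.ped, covariates=covariates)
    if snv is not None:
        dose = simdata.genotypes.loc[snv]
        vals = dose[data.layout.rows["individual"]].to_numpy(dtype=float)
        data = data.with_column("dosage", vals)
    design = build_components(
        data.layout, kinship_matrices(simdata.ped), serial=not first_visit_only
    )
    return data, design


@pytest.fixture(scope="session")
def small_dataset():
    """20 nuclear families x 4 members x 3 visits with one causal SNV."""
    cfg = SimConfig(seed=2024, n_families=20, template=Nuclear(2),
                    snv_effects={0: 0.3})
    return simulate_dataset(cfg)
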