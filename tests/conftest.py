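import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bsaqtl as b
from bsaqtl import pipeline

settings.register_profile("fixed", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def study_cross_experiment():
    """One simulated study experiment shared across tests."""
    return pipeline.simulate_bsa_inputs(b.study_cross(seed=1))


@pytest.fixture(scope="session")
def filtered_sites(study_cross_experiment):
    return b.apply_filter_chain(study_cross_experiment.site_table).sites


@pytest.fixture()
def toy_site_table():
    """Three hand-written sites: clean SNP, an indel, and a low-depth SNP."""
    return pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "pos": [1000, 5000, 2000],
        "vclass": ["SNP", "INDEL", "SNP"],
        "indel_len": [0, 4, 0],
        "qual": [150.0, 120.0, 90.0],
        "pA_ref": [20, 15, 30], "pA_alt": [0, 1, 0],
        "pB_ref": [0, 0, 1], "pB_alt": [25, 18, 28],
        "ef_ref": [30, 12, 5], "ef_alt": [5, 20, 4],
        "lf_ref": [8, 25, 6], "lf_alt": [28, 9, 7],
    })


def genotypes_to_codes(genos: pd.DataFrame) -> pd.DataFrame:
    """0/1/2 numeric genotypes -> A/H/B fine-marker codes."""
    return genos.replace({0: "A", 1: "H", 2: "B"})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
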