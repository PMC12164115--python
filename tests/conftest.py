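import numpy as np
import pandas as pd
import pytest

from rvafdriver.io import MUTATION_COLUMNS, CohortTable


def make_cohort(rows, cancer_type="TEST"):
    """Build a CohortTable from terse row dicts; unspecified fields get
    innocuous defaults."""
    defaults = {
        "sample_id": "S1",
        "gene": "GENE1",
        "chrom": "chr1",
        "pos": 100,
        "ref_allele": "A",
        "alt_allele": "T",
        "var_class": "missense",
        "dna_vaf": 0.3,
        "dna_alt": 30,
        "dna_depth": 100,
        "rna_alt": 5,
        "rna_ref": 5,
        "nmd_score": np.nan,
        "purity": 0.6,
        "ncn": 2,
        "tcn": 2,
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["pos"] = 100 + 10 * i  # distinct, non-adjacent positions by default
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)[MUTATION_COLUMNS]
    return CohortTable(cancer_type=cancer_type, df=df)


@pytest.fixture
def mk():
    return make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
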