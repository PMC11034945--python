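import numpy as np
import pandas as pd
import pytest

from epipair import synthetic_data as syn
from epipair.io_cli.formats import SampleMeta


@pytest.fixture(scope="session")
def small_model():
    return syn.make_genome_model(n_chrom=2, n_genes=40, n_tfs=5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    params = syn.SimParams(n_af_reversed=3, n_at_induced=3, n_shared=3, n_age=3)
    return syn.simulate_cohort(small_model, n_pairs_af=4, n_pairs_at=4, params=params, seed=5)


@pytest.fixture
def toy_genes():
    return pd.DataFrame(
        {
            "gene_id": ["G1", "G2", "G3"],
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [10_000, 50_000, 10_000],
            "strand": ["+", "-", "+"],
            "start": [10_000, 48_000, 10_000],
            "end": [12_000, 50_000, 12_000],
        }
    )


def make_sample(sample_id="s1", subject_id="sub1", pair_id="P1", group="case",
                cohort="AF", fraction="NeuNpos", assay="RNA", replicate=1,
                sex="M", age=50.0, pmd=10.0):
    return SampleMeta(sample_id, subject_id, pair_id, group, cohort, fraction,
                      assay, replicate, sex, age, pmd)


@pytest.fixture
def sample_factory():
    return make_sample
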