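import pytest

from graftmobile import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """A compact accession pair: 40 transcripts, ~1% SNP density, 6 mobile."""
    return synthetic.generate_accession_pair(
        seed=11, n_transcripts=40, snp_density=0.01
    )


@pytest.fixture(scope="session")
def small_observations(small_truth):
    design = synthetic.reciprocal_design(small_truth.accessions)
    return synthetic.generate_graft_experiment(
        small_truth, design, depth=50.0, error_rate=0.002, replicates=3, seed=12
    )
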