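import pytest

from ctsnet.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort with the default 3-subtype / 2-4-3-labeler structure."""
    cfg = SimConfig(n_samples=400, n_genes=120,
                    n_signature_genes_per_subtype=10, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort without batch effects (identity batch spec)."""
    from ctsnet.synthetic import BatchSpec

    cfg = SimConfig(
        n_samples=300, n_genes=100, n_signature_genes_per_subtype=10,
        batch_spec=(BatchSpec("single"),), seed=11,
    )
    return generate_cohort(cfg)
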