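import pytest

from aletools.simulate import simulate_reference


@pytest.fixture(scope="session")
def reference():
    """One deterministic 50 kb genome with 20 genes, shared across tests."""
    genome, genes, categories = simulate_reference(
        n_replicons=1, lengths=(50_000,), gc_content=0.5, n_genes=20, seed=1
    )
    return genome, genes, categories
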