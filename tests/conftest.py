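import pytest

from oglysite.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared (read-only) across test modules."""
    cfg = GeneratorConfig(
        n_proteins=30,
        mean_length=350.0,
        n_clustered_runs=30,
        n_isolated_sites=40,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_dataset():
    """Dataset whose isolated positives all carry Pro at −1 and whose
    negatives never do (deterministic, linearly separable motif)."""
    cfg = GeneratorConfig(
        n_proteins=40,
        mean_length=350.0,
        n_clustered_runs=40,
        n_isolated_sites=60,
        motif_probs={(-1, "P"): 1.0},
        exclusive_motifs=True,
        seed=3,
    )
    return generate_dataset(cfg)
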