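import pytest

from mirmint.synthetic_data import GeneratorConfig, design_for, generate_counts, \
    generate_mirnas, generate_utrs


@pytest.fixture(scope="session")
def default_config():
    """The default simulated study at a fixed seed."""
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def default_study(default_config):
    """Counts, sequences and truth of the default study (generated once)."""
    mirna_counts, mrna_counts, truth = generate_counts(default_config)
    mirnas = generate_mirnas(default_config)
    utrs, truth = generate_utrs(default_config, truth, mirnas)
    return {
        "config": default_config,
        "design": design_for(default_config),
        "mirna_counts": mirna_counts,
        "mrna_counts": mrna_counts,
        "mirnas": mirnas,
        "utrs": utrs,
        "truth": truth,
    }


@pytest.fixture
def small_config():
    """A fast, small study for unit-level checks."""
    return GeneratorConfig(
        seed=11,
        n_mirna=20,
        n_mrna=60,
        n_de_mirna_up=4,
        n_de_mirna_down=4,
        n_de_mrna_up=12,
        n_de_mrna_down=12,
        n_true_pairs=10,
        n_reads=200,
        n_terms=10,
        genes_per_term=8,
        n_enriched_terms=2,
        enriched_term_overlap=6,
    )
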