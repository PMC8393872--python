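import pytest

from mirnet import pipeline, synthetic


@pytest.fixture(scope="session")
def default_config():
    """Default study conditions: 5000 genes, 200 targets, 15 hubs."""
    return synthetic.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_data(default_config):
    return synthetic.simulate_all(default_config)


@pytest.fixture(scope="session")
def default_report(default_config):
    cfg = pipeline.PipelineConfig(simulation=default_config, seed=default_config.seed)
    return pipeline.run_all(cfg)


@pytest.fixture(scope="session")
def default_metrics(default_report, default_data):
    return pipeline.evaluate_recovery(default_report, default_data.truth)


@pytest.fixture(scope="session")
def null_config():
    """No planted effects anywhere: every selection should behave nominally."""
    return synthetic.SimulationConfig(
        seed=13,
        pulldown_enrichment_fold=1.0,
        transcript_effect=0.0,
        protein_effect=0.0,
        n_hubs=0,
        n_enriched_genesets=0,
        geneset_target_fraction=0.0,
    )


@pytest.fixture(scope="session")
def null_report(null_config):
    cfg = pipeline.PipelineConfig(simulation=null_config, seed=null_config.seed)
    return pipeline.run_all(cfg)


@pytest.fixture()
def small_config():
    """Scaled-down universe for fast unit-level pipeline runs."""
    return synthetic.SimulationConfig(
        n_genes=300,
        n_targets=40,
        utr_length_mean=300,
        utr_length_sd=60,
        n_hubs=5,
        hub_extra_degree=60,
        n_genesets=30,
        n_enriched_genesets=3,
        geneset_size_range=(10, 40),
        seed=11,
    )
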