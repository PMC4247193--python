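import pytest

from drnatss.config import PipelineConfig
from drnatss.simulate import SimulationParams, generate_genome, simulate_all_coverage
from drnatss import pipeline


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig.default()


@pytest.fixture(scope="session")
def sim200(cfg):
    """Default-scale study conditions: 200 genes, depth 40, Poisson noise."""
    params = SimulationParams(n_genes=200, seed=7)
    return params, pipeline.run_pipeline(params, cfg)


@pytest.fixture(scope="session")
def sim900(cfg):
    """Large genome: >=500 p/sTSS mRNA records, >=300 aTSS, 25 planted
    start-codon mis-annotations."""
    params = SimulationParams(n_genes=900, misannotation_count=25, seed=3)
    return params, pipeline.run_pipeline(params, cfg)


@pytest.fixture(scope="session")
def sim900_truth_records(sim900, cfg):
    """Noise-free classified records built from the planted TSS of sim900."""
    params, res = sim900
    return pipeline.records_from_truth(res.original_annotation, res.truth, cfg)
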