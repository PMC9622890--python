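import pytest

from damtarget.synthetic import (
    SimulationConfig,
    simulate_celltype_counts,
    simulate_damid,
    simulate_depletion_experiment,
    simulate_genome_with_motifs,
    simulate_joint_experiment,
)


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """The study-shaped default conditions at seed 1."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def celltype_sim(study_config):
    return simulate_celltype_counts(study_config)


@pytest.fixture(scope="session")
def depletion_sim(study_config, celltype_sim):
    _, truth = celltype_sim
    return simulate_depletion_experiment(truth, study_config)


@pytest.fixture(scope="session")
def genome_sim(study_config):
    return simulate_genome_with_motifs(study_config)


@pytest.fixture(scope="session")
def damid_sim(study_config, genome_sim):
    genome, genes, truth = genome_sim
    return simulate_damid(genome, genes, study_config)


@pytest.fixture(scope="session")
def joint_sim(study_config):
    return simulate_joint_experiment(study_config)
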