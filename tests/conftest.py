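"""Shared fixtures: one default simulation reused across the suite."""

from __future__ import annotations

import pytest

from seqbug.correction import classify_pileup
from seqbug.simulate import SimulationConfig, simulate_pileup, simulate_truth


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim(default_config):
    """(true_genome, gtf_text, truth) for the default 100 kb simulation."""
    return simulate_truth(default_config)


@pytest.fixture(scope="session")
def pileup_same(sim, default_config):
    _, _, truth = sim
    return simulate_pileup(truth, default_config, individual="same")


@pytest.fixture(scope="session")
def decisions(pileup_same):
    return list(classify_pileup(pileup_same))


@pytest.fixture(scope="session")
def gtf_file(tmp_path_factory, sim):
    _, gtf_text, _ = sim
    path = tmp_path_factory.mktemp("gtf") / "genes.gtf"
    path.write_text(gtf_text)
    return path
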