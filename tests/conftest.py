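"""Shared fixtures: a small synthetic benchmark and its pipeline run.

Session scope amortises the cost of dataset generation and the full
pipeline across the tests that inspect different aspects of the result.
"""

from __future__ import annotations

import pytest

from ice_scout.pipeline import RunConfig, run_pipeline
from ice_scout.synthetic import SimConfig, build_detection_hmms, generate_dataset


@pytest.fixture(scope="session")
def mini_config() -> SimConfig:
    return SimConfig(seed=7, n_genomes=12)


@pytest.fixture(scope="session")
def mini_dataset(mini_config):
    return generate_dataset(mini_config)


@pytest.fixture(scope="session")
def mini_hmms(mini_dataset):
    return build_detection_hmms(mini_dataset.templates)


@pytest.fixture(scope="session")
def mini_result(mini_dataset, mini_hmms):
    return run_pipeline(
        mini_dataset.genomes,
        mini_hmms,
        RunConfig(),
        plasmid_virb4=mini_dataset.plasmid_virb4,
    )


def truth_ice_for(candidate, manifest):
    """The manifest row of the planted ICE a candidate falls into."""
    for row in manifest["genomes"][candidate.genome_id]["ices"]:
        lo = row["start"]
        hi = row["end"]
        if candidate.region_start is not None and lo <= candidate.region_start and candidate.region_end <= hi:
            return row
        member_mid = (candidate.region_start or lo) + 1
        if lo <= member_mid <= hi:
            return row
    return None
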