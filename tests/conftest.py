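from __future__ import annotations

import pytest

from apmsflow.model import (
    BAIT,
    CONTROL,
    CountMatrix,
    ProteinRecord,
    Sample,
    SampleDesign,
)
from apmsflow.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture
def tiny_design() -> SampleDesign:
    return SampleDesign(
        [
            Sample("A4_BAIT_1", "A4", BAIT, 1),
            Sample("A4_BAIT_2", "A4", BAIT, 2),
            Sample("A4_CTRL_1", "A4", CONTROL, 1),
            Sample("A4_CTRL_2", "A4", CONTROL, 2),
        ]
    )


@pytest.fixture
def tiny_matrix(tiny_design) -> CountMatrix:
    def rec(acc, sym, counts):
        return ProteinRecord(
            accession=acc,
            gene_symbol=sym,
            counts=dict(zip(tiny_design.sample_ids, counts)),
            probability=0.99,
            n_unique_peptides=3,
        )

    return CountMatrix(
        proteins=[
            rec("P1", "TLN1", (8, 9, 1, 1)),
            rec("P2", "HSPA9", (1, 0, 20, 24)),
            rec("P3", "ACTB", (5, 5, 5, 5)),
        ],
        design=tiny_design,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=7,
        n_planted_per_region=4,
        n_background=20,
        n_reagent=10,
        n_other=80,
        n_extra_nodes=30,
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    simulate_bundle(small_config, out)
    return out
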