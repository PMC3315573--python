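"""Shared fixtures: one small simulated reference reused across mapping tests."""

from __future__ import annotations

import pytest

from tagomics import synthetic


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimConfig:
    return synthetic.SimConfig(
        n_genes=60,
        n_de_genes=10,
        log2_fc_values=(2.0, 3.0),
        library_sizes=(40_000, 40_000),
        gene_length_range=(300, 900),
        intergenic_length_range=(100, 400),
        cleavage_prob=0.8,
        antisense_rate=0.1,
        seq_error_rate=0.0,
        intron_rate=0.0,
        utr_unannotated_bp=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    genome, models, truth = synthetic.generate_reference(small_config)
    return genome, models, truth


@pytest.fixture(scope="session")
def small_libraries(small_config, small_reference):
    genome, models, truth = small_reference
    lib1, lib2, truth = synthetic.simulate_tag_libraries(
        (genome, models), truth, small_config
    )
    return lib1, lib2, truth
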