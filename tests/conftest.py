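"""Shared fixtures: scaled-down default fixtures for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from bcellpipe.repertoire import assign_germline_many, build_clonotype_table
from bcellpipe.synthetic import (
    ExpressionConfig,
    HashtagConfig,
    RepertoireConfig,
    SprConfig,
    default_reference,
    simulate_expression,
    simulate_hashtags,
    simulate_repertoire,
    simulate_sensorgram,
)


@pytest.fixture(scope="session")
def reference():
    return default_reference("NOD")


@pytest.fixture(scope="session")
def small_repertoire(reference):
    """~760-cell three-mouse fixture with default clonotype probabilities."""
    config = RepertoireConfig(cells_per_mouse=(400, 330, 30))
    table, truth = simulate_repertoire(config, seed=11, reference=reference)
    return config, table, truth


@pytest.fixture(scope="session")
def small_clonotype_table(small_repertoire, reference):
    _, table, truth = small_repertoire
    kappa = table.chain("IGK")
    seqs = {cid: table.sequences[cid] for cid in kappa["contig_id"]}
    calls = assign_germline_many(seqs, reference)
    return build_clonotype_table(table, calls)


@pytest.fixture(scope="session")
def default_hashtag_fixture():
    config = RepertoireConfig()
    _, truth = simulate_repertoire(config, seed=5)
    ht_config = HashtagConfig()
    matrix, ht_truth = simulate_hashtags(ht_config, truth["donor"].to_numpy(), seed=6)
    return config, ht_config, matrix, ht_truth


@pytest.fixture(scope="session")
def expression_fixture():
    config = ExpressionConfig()
    counts, labels = simulate_expression(config, seed=3)
    return config, counts, labels


@pytest.fixture(scope="session")
def noise_free_sensorgrams():
    config = SprConfig(noise_sd=0.0, baseline_offset=0.0)
    return config, simulate_sensorgram(config, seed=0)
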