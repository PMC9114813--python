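"""Shared fixtures: one small simulated study reused across module tests.

The small study (300 genes, 10 planted orphans, one duplicate pair of each
mode) is expensive enough that cascade and origin results are computed once
per session and shared."""

from __future__ import annotations

import pytest

from orphanforge.cascade import run_cascade
from orphanforge.origins import classify_origins
from orphanforge.synthetic import SimConfig, simulate_study

SMALL_SEED = 11


def small_config(seed: int = SMALL_SEED) -> SimConfig:
    return SimConfig(
        seed=seed, n_genes=300, n_chromosomes=3,
        duplication_plan={"tandem": 1, "proximal": 1, "dispersed": 1,
                          "wgd": 1, "transposed": 1},
        te_gene_count=2, overlap_gene_count=2, denovo_gene_count=2,
        plain_orphan_count=2)


@pytest.fixture(scope="session")
def study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def cascade_summary(study):
    return run_cascade(study.package.genes, study.panel)


@pytest.fixture(scope="session")
def origin_calls(study, cascade_summary):
    calls, counts = classify_origins(sorted(cascade_summary.orphan_ids),
                                     study.package, study.context)
    return calls, counts
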