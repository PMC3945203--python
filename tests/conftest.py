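"""Shared fixtures: two session-scoped synthetic experiments.

``clean_run`` is a small error-free experiment used for exactness
properties (assignment purity, SNP class truth, linkage assignment).
``default_run`` is the study-condition-scale experiment used for the
statistical recovery properties; it is the expensive fixture, built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from homeosort import pipeline
from homeosort.simulate import SimConfig


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    return SimConfig(
        n_genes=60,
        library_sizes=(15_000, 15_000, 25_000),
        n_replicates=1,
        error_rate=0.0,
        n_deletion_clusters=2,
        deletion_cluster_size=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_run(clean_cfg) -> pipeline.PipelineResult:
    return pipeline.run(clean_cfg)


@pytest.fixture(scope="session")
def default_run() -> pipeline.PipelineResult:
    return pipeline.run(SimConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def _assignment_detail(result: pipeline.PipelineResult):
    """Per-fragment assignment for replicate 0 of an experiment."""
    from homeosort.expression import assign_reads
    from homeosort.seqmap import KmerIndex

    refs = result.refs
    retained = sorted(g for g, r in refs.items() if r.retained)
    idx1 = KmerIndex({g: refs[g].p1_like for g in retained}, k=31)
    idx2 = KmerIndex({g: refs[g].p2_like for g in retained}, k=31)
    rs = result.sim.reads["allo"][0]
    _, _, detail = assign_reads(rs, idx1, idx2, retained)
    return rs, detail


@pytest.fixture(scope="session")
def clean_assignment(clean_run):
    """Error-free per-fragment assignment detail (for purity checks)."""
    return _assignment_detail(clean_run)


@pytest.fixture(scope="session")
def default_assignment(default_run):
    """Error-rate 1e-3 per-fragment assignment detail."""
    return _assignment_detail(default_run)
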