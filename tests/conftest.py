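"""Shared fixtures: small simulation configs and a full default pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from crossbind import pipeline
from crossbind.intervals import GenomicInterval, PeakSet
from crossbind.synthetic_data import ExpressionPlan, MotifPlan, SimulationConfig


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     span: int = 10_000, max_width: int = 400) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out


def brute_force_overlap(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    return a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= min_bp


@pytest.fixture(scope="session")
def default_bundle() -> pipeline.ResultsBundle:
    """One full pipeline run on the default simulation (seed 0), reused read-only."""
    return pipeline.run_all(pipeline.RunConfig(sim=SimulationConfig(seed=0)))


@pytest.fixture()
def tiny_expression_config() -> SimulationConfig:
    """Small genome/gene-count config for expression-focused tests."""
    return SimulationConfig(
        genome_length=3_000_000,
        n_chromosomes=2,
        peaks_per_class={"specific": 5, "CNS-common": 2, "endoderm-common": 2, "all-common": 2},
        spurious_per_tissue=0,
        n_genes=400,
        expression_plan=ExpressionPlan(n_specific_extra=10),
        seed=7,
    )
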