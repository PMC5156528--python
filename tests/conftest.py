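"""Shared fixtures: a small annotated genome and a full synthetic timecourse.

Session-scoped so the expensive end-to-end objects (pooled per-cycle peak
calls for both genotypes) are computed once and shared by the feature,
timing, and dependence tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import embryoatac as ea
from embryoatac.synthetic import default_timepoint_grid


@pytest.fixture(scope="session")
def genome():
    return ea.make_genome(ea.GenomeConfig(), seed=3)


@pytest.fixture(scope="session")
def nc13_sample(genome):
    spec = ea.SampleSpec("diploid", 13, 6.0, "interphase", 40_000, seed=5)
    return ea.sample_fragments(genome, spec)


@pytest.fixture(scope="session")
def open_nuc_split(nc13_sample):
    return ea.split_by_length(nc13_sample)


def _series_calls(genome, genotype, seed):
    series = ea.make_series(
        genome, genotype, default_timepoint_grid(genotype), seed=seed, n_fragments=40_000
    )
    per_cycle = {}
    for cyc in sorted({fs.metadata["cycle"] for fs in series}):
        pooled = ea.pool(series, by={"cycle": cyc})
        o, _ = ea.split_by_length(pooled)
        per_cycle[cyc] = ea.call_peaks(o, genome.chrom_sizes)
    o, _ = ea.split_by_length(ea.pool(series))
    union = ea.call_peaks(o, genome.chrom_sizes)
    return series, per_cycle, union


@pytest.fixture(scope="session")
def diploid_run(genome):
    return _series_calls(genome, "diploid", seed=21)


@pytest.fixture(scope="session")
def haploid_run(genome):
    return _series_calls(genome, "haploid", seed=22)


@pytest.fixture(scope="session")
def diploid_timing(genome, diploid_run):
    _, per_cycle, union = diploid_run
    return ea.assign_timing(union, per_cycle)


def match_truth_to_calls(truth: pd.DataFrame, called: pd.DataFrame, column: str):
    """For each truth peak, the value of ``column`` on an overlapping call."""
    out = []
    for _, t in truth.iterrows():
        sel = called[
            (called["chrom"] == t["chrom"]) & (called["start"] < t["end"]) & (called["end"] > t["start"])
        ]
        out.append(sel.iloc[0][column] if len(sel) else None)
    return np.array(out, dtype=object)
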