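"""Shared fixtures: the default synthetic runs are expensive (whole-pipeline
liftover on a ~3 Mb genome), so they are built once per session."""

from __future__ import annotations

import pytest

from gapscope.config import AnalysisConfig
from gapscope.gap_cause import run_gap_analysis
from gapscope.synthetic_data import SimulationConfig, build_truth_genome, derive_draft


@pytest.fixture(scope="session")
def analysis_cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def truth1():
    """Default study conditions, seed 1, no mutation."""
    return build_truth_genome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def draft1(truth1):
    return derive_draft(truth1)


@pytest.fixture(scope="session")
def gap_result1(truth1, draft1, analysis_cfg):
    return run_gap_analysis(
        draft1.draft, truth1.genome, draft1.draft_repeats, truth1.repeats, analysis_cfg
    )


@pytest.fixture(scope="session")
def truth_mut():
    """Same conditions with 1% per-base draft mutation."""
    return build_truth_genome(SimulationConfig(seed=1, mutation_rate=0.01))


@pytest.fixture(scope="session")
def draft_mut(truth_mut):
    return derive_draft(truth_mut)


@pytest.fixture(scope="session")
def gap_result_mut(truth_mut, draft_mut, analysis_cfg):
    return run_gap_analysis(
        draft_mut.draft, truth_mut.genome, draft_mut.draft_repeats, truth_mut.repeats,
        analysis_cfg,
    )


def gap_truth_by_position(draft_truth):
    return {(g.scaffold, g.start, g.end): g for g in draft_truth.gap_truth}
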