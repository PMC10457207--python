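"""Shared fixtures: one full default pipeline run reused across the suite."""

import logging

import numpy as np
import pytest
from hypothesis import settings

from lineagewave.pipeline import PipelineConfig, run_all
from lineagewave.simdata import SimConfig, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

logging.getLogger("lineagewave").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_sim():
    """Modest simulated dataset (600 cells) for unit-level checks."""
    cfg = SimConfig(n_cells_per_genotype=200, seed=7)
    bundle, truth = simulate_dataset(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run (~2,000 cells) shared by the suite."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(seed=1, outdir=str(outdir))
    report, state = run_all(config, write_outputs=True, return_state=True)
    assert report.failed_stage is None, report.stage_status
    return config, report, state


@pytest.fixture(scope="session")
def truth_arrays(pipeline_run):
    """Convenience arrays aligned with the pipeline's QC-filtered cells."""
    _, _, state = pipeline_run
    tc = state["truth_cells"]
    return {
        "t": tc["true_pseudotime"].to_numpy(),
        "lineage": tc["true_lineage"].to_numpy(),
        "stage": tc["true_stage"].to_numpy(),
        "genotype": tc["genotype"].to_numpy(),
        "restricted": tc["genotype"].isin(
            ["MHC2_restricted", "MHC1_restricted"]).to_numpy(),
    }


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
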