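"""Shared fixtures: one default synthetic dataset and one full pipeline run,
generated once per session and reused by unit and acceptance tests."""

from __future__ import annotations

import pytest

from shearmap.pipeline import Pipeline, PipelineConfig
from shearmap.synthetic import SynthConfig, generate_dataset, read_truth

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-condition synthetic dataset (seed 1): (data_dir, truth)."""
    d = tmp_path_factory.mktemp("synth_default")
    _, truth = generate_dataset(SynthConfig(seed=DEFAULT_SEED), d)
    return d, truth


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run on the default dataset: (Pipeline, summary, truth)."""
    data_dir, truth = default_dataset
    outdir = tmp_path_factory.mktemp("run_default")
    pipe = Pipeline(
        PipelineConfig(data_dir=str(data_dir), outdir=str(outdir), seed=DEFAULT_SEED)
    )
    summary = pipe.run_all()
    return pipe, summary, truth
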