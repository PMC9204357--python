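"""Shared fixtures: one small synthetic dataset and one fitted model.

The session-scoped fitted model (6 clips, 48x48 px, ~1.5 s each) is the
workhorse for the integration-level tests; module-level unit tests build
their own tiny inputs.
"""

import numpy as np
import pytest

from dynaface import fixtures, pipeline

SESSION_SEED = 11


@pytest.fixture(scope="session")
def fixture_config():
    return fixtures.FixtureConfig()


@pytest.fixture(scope="session")
def dataset(fixture_config):
    """(clips, truths) for a 6-clip synthetic dataset."""
    return fixtures.make_dataset(6, fixture_config, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def fitted(dataset):
    """(AppearanceModel, report) fitted on the session dataset."""
    clips, _ = dataset
    cfg = pipeline.PipelineConfig(out_size=48)
    with np.errstate(all="ignore"):
        return pipeline.fit_appearance_model(
            [s for s, _ in clips], [a for _, a in clips], cfg)


@pytest.fixture(scope="session")
def base_image():
    return fixtures.make_base_image(48, 48, seed=5)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A small 3-clip dataset written to disk (32 px frames)."""
    cfg = fixtures.FixtureConfig(height=32, width=32)
    clips, truths = fixtures.make_dataset(3, cfg, seed=4)
    path = tmp_path_factory.mktemp("dataset")
    fixtures.write_dataset(path, clips, truths)
    return path
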