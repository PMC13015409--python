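import warnings

import pytest

from chromlink import RunConfig, SyntheticConfig, generate_dataset, run_pipeline
from chromlink.synthetic import load_manifest


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """Default synthetic dataset, generated once per session."""
    d = tmp_path_factory.mktemp("dataset")
    generate_dataset(SyntheticConfig(seed=11), d)
    return d


@pytest.fixture(scope="session")
def manifest(dataset_dir):
    return load_manifest(dataset_dir)


@pytest.fixture(scope="session")
def pipeline_result(dataset_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            RunConfig(dataset_dir=str(dataset_dir), output_dir=str(out))
        )
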