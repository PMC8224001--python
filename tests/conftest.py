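import warnings

import pytest

from keramine.config import PipelineConfig
from keramine.pipeline import PipelineInputs, run_pipeline
from keramine.simulate import gen_keratinase_scenario


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """The minimal planted scenario, written to disk and run end to end."""
    workdir = tmp_path_factory.mktemp("scenario")
    bundle = gen_keratinase_scenario(seed=1)
    bundle.write(workdir)
    config = PipelineConfig(random_seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(
            config, PipelineInputs.from_bundle_dir(workdir), workdir / "out"
        )
    return bundle, workdir, result
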