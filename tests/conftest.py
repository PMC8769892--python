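import numpy as np
import pytest

from csgcn.synthetic_data import SyntheticConfig, generate_dataset
from csgcn.workflow import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A reduced planted scenario with the full pipeline already run.

    Shared across tests that only need *some* realistic pipeline output;
    the acceptance tests run the full-size default scenario themselves.
    """
    cfg = SyntheticConfig(n_bimodal=3, n_category=3, n_spoke=2,
                          n_confounded=3, n_basal=2, n_null=3, seed=11)
    gem, annotations, truth = generate_dataset(cfg)
    out = tmp_path_factory.mktemp("small") / "run"
    pipe = PipelineConfig(out_prefix=str(out), quantitative_vars=["Time"],
                          seed=11)
    result = run_pipeline(pipe, gem=gem, annotations=annotations)
    return {"config": cfg, "gem": gem, "annotations": annotations,
            "truth": truth, "pipeline": pipe, "run": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
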