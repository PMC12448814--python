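import logging

import pytest

from rhizomix import RunConfig, run_pipeline

logging.getLogger("rhizomix").setLevel(logging.ERROR)
logging.getLogger("py.warnings").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full pipeline run under the default (full-scale, arms-race)
    scenario; shared across tests that inspect its outputs."""
    out = tmp_path_factory.mktemp("study_run")
    config = RunConfig(scenario="arms_race", seed=1, out_dir=str(out))
    report = run_pipeline(config)
    return {"report": report, "out": out, "config": config}


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """Pipeline run under the no-interaction scenario (theta = delta = 0)."""
    out = tmp_path_factory.mktemp("null_run")
    config = RunConfig(scenario="null", seed=1, out_dir=str(out))
    report = run_pipeline(config)
    return {"report": report, "out": out, "config": config}
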