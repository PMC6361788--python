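import numpy as np
import pytest

from mirgo import pipeline
from mirgo.synthetic import default_fixture, fixture_pipeline_params, simulate


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The canonical synthetic data set (written once per session)."""
    path = tmp_path_factory.mktemp("fixture")
    gt = simulate(default_fixture(), str(path))
    return path, gt


def _e2e(data_dir, use_ppi=True, seed=1):
    params = fixture_pipeline_params()
    ep = {k: params[k] for k in
          ("walks_per_node", "walk_length", "window", "dim", "epochs")}
    sp = {"c_grid": params["c_grid"], "g_grid": params["g_grid"],
          "folds": params["folds"]}
    return pipeline.run_end_to_end(
        str(data_dir), use_ppi=use_ppi, seed=seed,
        embed_params=ep, svm_params=sp, min_pos=params["min_pos"],
    )


@pytest.fixture(scope="session")
def fixture_e2e(fixture_dir):
    """Full pipeline result on the canonical fixture (run once)."""
    path, _ = fixture_dir
    return _e2e(path)


@pytest.fixture(scope="session")
def fixture_e2e_no_ppi(fixture_dir):
    """Pipeline result with the PPI block zeroed (ablation)."""
    path, _ = fixture_dir
    return _e2e(path, use_ppi=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_obo_text(path, stanzas):
    """Write a minimal OBO 1.2 file from lists of stanza lines."""
    lines = ["format-version: 1.2", "ontology: test", ""]
    for s in stanzas:
        lines.append("[Term]")
        lines.extend(s)
        lines.append("")
    path.write_text("\n".join(lines))
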