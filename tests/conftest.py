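"""Shared fixtures: one session-scoped synthetic bundle and pipeline run."""

from __future__ import annotations

import pytest

from ernanet.pipeline import RunConfig, run_pipeline
from ernanet.synth import SyntheticConfig, generate_bundle, write_bundle


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def run_dir(bundle_dir, tmp_path_factory):
    d = tmp_path_factory.mktemp("run")
    run_pipeline(RunConfig(str(bundle_dir), str(d), seed=0))
    return d


@pytest.fixture(scope="session")
def run_report(run_dir):
    import json

    return json.loads((run_dir / "report.json").read_text())
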