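import pathlib

import pytest

from ppre.synthetic_data import (
    GeneratorConfig,
    SyntheticTruth,
    kinase_panel_config,
    write_fixture,
)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory) -> pathlib.Path:
    """Default small fixture: 1 x 100 kb chromosome, 12 '+' / 8 '-' sites."""
    out = tmp_path_factory.mktemp("fixture-small")
    return write_fixture(GeneratorConfig(seed=11), out / "fx")


@pytest.fixture(scope="session")
def panel_fixture(tmp_path_factory) -> pathlib.Path:
    """Paper-shaped fixture: 29 query kinases with the reported degree spread."""
    out = tmp_path_factory.mktemp("fixture-panel")
    return write_fixture(kinase_panel_config(seed=11), out / "fx")


@pytest.fixture(scope="session")
def small_truth(small_fixture) -> SyntheticTruth:
    return SyntheticTruth.from_json((small_fixture / "truth.json").read_text())


@pytest.fixture(scope="session")
def panel_truth(panel_fixture) -> SyntheticTruth:
    return SyntheticTruth.from_json((panel_fixture / "truth.json").read_text())
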