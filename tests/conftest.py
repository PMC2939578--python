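import numpy as np
import pytest

from thermobias import datasets, synthetic


@pytest.fixture
def write_text(tmp_path):
    """Write a small text fixture file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write


@pytest.fixture(scope="session")
def vertebrate_table():
    return datasets.vertebrate_panel()


@pytest.fixture(scope="session")
def small_panel():
    """10-species panel at reduced proteome size, for fast pipeline tests."""
    cfg = synthetic.GeneratorConfig(
        n_species=10, n_proteins=30, length_range=(80, 160), seed=42
    )
    return synthetic.simulate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
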