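import numpy as np
import pytest

from mirpanel.diffexpr import Contrast, normalize_delta_ct, run_contrast
from mirpanel.panel_io import PanelLayout
from mirpanel.synthetic_data import default_study_config, make_layout, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_layout():
    return make_layout(n_targets=5, n_controls=2)


@pytest.fixture(scope="session")
def null_panel():
    """Study-shaped null panel (no planted effects), shared across tests."""
    config = default_study_config(seed=7)
    layout = make_layout(n_targets=config.n_target_assays)
    ct_table, meta = simulate_panel(config, layout)
    return ct_table, meta


@pytest.fixture(scope="session")
def null_dct(null_panel):
    ct_table, _ = null_panel
    return normalize_delta_ct(ct_table)


@pytest.fixture(scope="session")
def cancer_contrast(null_panel):
    _, meta = null_panel
    a = tuple(m.sample_id for m in meta if m.group == "cancer")
    b = tuple(m.sample_id for m in meta if m.group == "healthy")
    return Contrast("cancer_vs_healthy", a, b)


@pytest.fixture(scope="session")
def null_de(null_dct, cancer_contrast):
    return run_contrast(null_dct, cancer_contrast)
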