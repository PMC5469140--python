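import warnings

import pandas as pd
import pytest

from inbrex.axes import derive_axes
from inbrex.simulate import SimConfig, generate_line_fitness, generate_lineage_histories


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale configuration for fast survival-model tests."""
    return SimConfig(n_lines=15, lineages_per_line=12, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    lines = generate_line_fitness(small_cfg)
    records, truth = generate_lineage_histories(lines, small_cfg)
    axes = derive_axes(lines)
    return {"lines": lines, "records": records, "truth": truth, "axes": axes}


@pytest.fixture(scope="session")
def default_dataset():
    """One default-size (41 x 20, continuous-time) simulated experiment."""
    cfg = SimConfig(seed=42)
    lines = generate_line_fitness(cfg)
    records, truth = generate_lineage_histories(lines, cfg)
    return {"cfg": cfg, "lines": lines, "records": records, "truth": truth,
            "axes": derive_axes(lines)}


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        yield


@pytest.fixture
def toy_survival():
    """Six records, distinct times, one covariate; small enough to check the
    partial likelihood against a directly coded oracle."""
    return pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 0, 1, 1, 0],
        "x": [1.0, 0.0, 1.0, 0.5, -0.5, 0.0],
    })
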