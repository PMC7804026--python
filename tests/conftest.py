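import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from respirocod import OURSeries, SimulationConfig, paper_fixture


@pytest.fixture
def table2():
    return paper_fixture("table2_forward")


@pytest.fixture
def table3():
    return paper_fixture("table3_sequential")


@pytest.fixture
def table4():
    return paper_fixture("table4_reverse")


@pytest.fixture
def cod_mixture():
    return paper_fixture("cod_mixture")


@pytest.fixture
def fast_sim_config():
    """A small, quickly depleting scenario for end-to-end tests."""
    return SimulationConfig(ss0=40.0, xs0=100.0, duration_min=340.0,
                            sample_interval_min=2.0, noise_sd_frac=0.0)


def make_series(times, values, label="test"):
    return OURSeries(np.asarray(times, float), np.asarray(values, float),
                     label=label)
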