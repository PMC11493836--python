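import pytest

from gslmrm import panel as panel_mod
from gslmrm import quant as quant_mod
from gslmrm import simulate as sim_mod
from gslmrm.cohort import load_cohort_table


@pytest.fixture(scope="session")
def default_config():
    return panel_mod.default_panel_config()


@pytest.fixture(scope="session")
def default_panel(default_config):
    return panel_mod.build_panel(default_config)


@pytest.fixture(scope="session")
def cohort_table():
    return load_cohort_table()


@pytest.fixture(scope="session")
def calibrations(default_panel, default_config):
    """Per-species calibrations from a simulated 3-replicate 7-point
    1:4 dilution series at default acquisition noise."""
    plans = sim_mod.make_calibration_series(replicates=3, seed=1234)
    chroms = sim_mod.simulate_plans(default_panel, plans)
    q = quant_mod.quantify_all(chroms, default_panel, default_config.is_map)
    truth = {p.sample_id: p.amounts["GM3 d36:1"] for p in plans}
    return quant_mod.calibrate_from_records(q, truth)
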