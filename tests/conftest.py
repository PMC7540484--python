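import numpy as np
import pytest

from somsorb import synthetic_data


@pytest.fixture(scope="session")
def table1():
    return synthetic_data.table1_fixture()


@pytest.fixture(scope="session")
def table1_columns(table1):
    """Table columns as arrays keyed by quantity."""
    return {
        "dry_calc": np.array([r.dg_dry_calc for r in table1]),
        "dry_err": np.array([r.dg_dry_err for r in table1]),
        "hyd_calc": np.array([r.dg_hyd_calc for r in table1]),
        "hyd_err": np.array([r.dg_hyd_err for r in table1]),
        "ddg_calc": np.array([r.ddg_calc for r in table1]),
        "ddg_err": np.array([r.ddg_err for r in table1]),
        "exp_dry": np.array([r.ddg_exp_dry for r in table1]),
        "exp_hyd": np.array([r.ddg_exp_hyd for r in table1]),
    }
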