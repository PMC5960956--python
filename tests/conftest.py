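import numpy as np
import pandas as pd
import pytest

from microferm import balance as bal
from microferm import presets as pre
from microferm import simulate as sim
from microferm import speciation as spc


@pytest.fixture(scope="session")
def yeast():
    return pre.get_preset("yeast_lysate")


@pytest.fixture(scope="session")
def rna():
    return pre.get_preset("yeast_rna")


@pytest.fixture(scope="session")
def bsa():
    return pre.get_preset("bsa_protein")


@pytest.fixture
def geometry():
    return spc.VialGeometry(total_ml=27.0, liquid_ml=10.0, fresh_weight_g=1.0)


@pytest.fixture
def lysate_substrate():
    return bal.SubstrateSpec(
        label="lysate", n_c_umol=2290.0, n_r_c=4.019, kind="biomass"
    )


def make_scenario(substrate=None, **overrides):
    """A small, valid fermentation scenario for pipeline tests."""
    if substrate is None:
        substrate = bal.SubstrateSpec(
            label="lysate", n_c_umol=2290.0, n_r_c=4.019, kind="biomass"
        )
    kwargs = dict(
        substrate=substrate,
        yields_carbon={
            "acetate": 0.202,
            "CO2": 0.052,
            "methyl_butyrate": 0.181,
            "succinate": 0.09,
        },
        h2_electron_yield=0.007,
        transient_peaks={"formate": 0.02},
        control_baseline={"acetate": 20.0, "CO2": 30.0},
        noise_rel_sd=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return sim.FermentationScenario(**kwargs)


@pytest.fixture
def scenario():
    return make_scenario()


def run_pipeline(scen, exclusion_tol=1e-9, at=None):
    """simulate -> speciate -> net -> recovery, returning the table and nets."""
    measurements, _ = sim.simulate_microcosm(scen)
    amounts = spc.speciate_table(measurements, scen.geometry, scen.constants)
    series = bal.TreatmentSeries.from_frame(amounts)
    t_arm = [s for s in series if s.treatment == "treatment"]
    c_arm = [s for s in series if s.treatment == "control"]
    nets = bal.net_products(t_arm, c_arm)
    table = bal.recovery_table(
        nets, scen.substrate, at=at, exclusion_tol=exclusion_tol
    )
    return table, nets


@pytest.fixture
def community_tables():
    """Small deterministic paired abundance tables in percent."""
    periods = [0.0, 10.0, 20.0, 30.0]
    treat = pd.DataFrame(
        {
            0.0: [10.0, 5.0, 2.0, 83.0],
            10.0: [12.0, 5.0, 3.5, 79.5],
            20.0: [10.0, 5.0, 3.0, 82.0],
            30.0: [10.0, 5.0, 2.5, 82.5],
        },
        index=["famA", "famB", "famC", "famD"],
    )
    ctrl = pd.DataFrame(
        {
            0.0: [10.0, 5.0, 2.0, 83.0],
            10.0: [5.0, 5.0, 2.0, 88.0],
            20.0: [10.0, 5.0, 2.0, 83.0],
            30.0: [10.0, 5.0, 2.0, 83.0],
        },
        index=["famA", "famB", "famC", "famD"],
    )
    return treat, ctrl, periods
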