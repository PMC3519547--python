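import numpy as np
import pytest

from lipidremodel import (
    InferenceConfig,
    bidirectionalize,
    build_ode,
    control_path_spec,
    grid_remodeling_spec,
    infer_network,
    simulate_pulse_chase,
    single_path_spec,
)
from lipidremodel.rate_analysis import load_reference_rate_tables


@pytest.fixture(scope="session")
def noiseless_path():
    """Noiseless 3-species conversion chain (precursor -> intermediate -> product)."""
    return simulate_pulse_chase(single_path_spec(noise_cv=0.0))


@pytest.fixture(scope="session")
def noisy_path():
    """Same chain with 10% multiplicative noise, fixed seed."""
    return simulate_pulse_chase(single_path_spec(noise_cv=0.10, seed=42))


@pytest.fixture(scope="session")
def control_data():
    """Five-species chain used for the negative controls (10% noise)."""
    return simulate_pulse_chase(control_path_spec(seed=11))


@pytest.fixture(scope="session")
def grid_data():
    """Six-species rank-1 remodeling grid (10% noise)."""
    return simulate_pulse_chase(grid_remodeling_spec(seed=11))


@pytest.fixture(scope="session")
def reference_tables():
    """Packaged BHK21 conversion-rate tables, one per sn position."""
    return load_reference_rate_tables()


@pytest.fixture(scope="session")
def fitted_noiseless_path(noiseless_path):
    """Inferred network + ODE system + fit on the noiseless chain."""
    from lipidremodel import fit_dynamics

    tc, truth = noiseless_path
    net = infer_network(tc, InferenceConfig())
    sys = build_ode(bidirectionalize(net))
    fit = fit_dynamics(tc, sys)
    return tc, truth, net, sys, fit
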