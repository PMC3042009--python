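import numpy as np
import pytest

from stat1kin import (
    NoiseSpec,
    OptimizerSettings,
    ParameterSpace,
    ParamSpec,
    demo_parameter_space,
    demo_truth,
    generate_dataset,
)

pytest_plugins: list[str] = []


@pytest.fixture(scope="session")
def demo_params():
    params, _ = demo_truth()
    return params


@pytest.fixture(scope="session")
def demo_sf():
    _, sf = demo_truth()
    return sf


@pytest.fixture(scope="session")
def theta_star(demo_params):
    """Truth values for every searched parameter of the demo space."""
    space = demo_parameter_space()
    return {
        name: getattr(demo_params, name)
        for name, spec in space.specs.items()
        if not spec.fixed and not name.startswith("WB_")
    }


@pytest.fixture(scope="session")
def noiseless_data(demo_params, demo_sf):
    noise = NoiseSpec(blot_cv=0, loading_cv=0, ct_sd=0, cell_ratio_cv=0, seed=1)
    return generate_dataset(demo_params, demo_sf, noise=noise)


@pytest.fixture(scope="session")
def noisy_data(demo_params, demo_sf):
    """Default-condition synthetic dataset: blot CV 0.2, 4 replicates."""
    return generate_dataset(demo_params, demo_sf, noise=NoiseSpec(seed=7))


@pytest.fixture()
def small_space(demo_params):
    """Two free kinetic parameters, everything else fixed at demo truth."""
    specs = [
        ParamSpec("k_act", 1e-5, 1e-2),
        ParamSpec("k_phos", 1e-4, 1e-1),
        ParamSpec("WB_STAT1", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1c", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1n", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1D", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1Dc", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1Dn", 1e-3, 1e6, scope="local"),
    ]
    return ParameterSpace(specs, base=demo_params)


@pytest.fixture()
def quick_settings():
    return OptimizerSettings(
        n_restarts=1, sa_iterations=50, local_max_iterations=20, seed=5
    )
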