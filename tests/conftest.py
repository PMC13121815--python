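import numpy as np
import pytest

import interdif as idf


@pytest.fixture(scope="session")
def tiny_data():
    """6 persons, 2 items, 2 groups — small enough for brute-force oracles."""
    rng = np.random.default_rng(3)
    design = idf.build_group_design([2])
    Y = rng.integers(0, 2, size=(6, 2)).astype(float)
    g = np.array([0, 0, 0, 1, 1, 1])
    return idf.ResponseData(Y=Y, group_of=g, design=design)


def make_params(design, variant, rng):
    """Random but valid parameters for a 2-item model of any variant."""
    P = design.P
    return idf.Parameters(
        intercept_base=np.array([0.2, -0.3]),
        intercept_main=rng.normal(0, 0.2, (2, P)),
        slope_base=np.array([1.2, 0.9]),
        slope_main=(
            rng.normal(0, 0.1, (2, P))
            if variant in ("Ris", "RisM")
            else np.zeros((2, P))
        ),
        var_intercept=np.array([0.4, 0.2]),
        var_slope=(
            np.array([0.3, 0.25]) if variant in ("Ris", "RisM") else np.zeros(2)
        ),
        impact_main=rng.normal(0, 0.2, P),
        impact_var=0.5 if variant in ("RiM", "RisM") else 0.0,
    )


@pytest.fixture(scope="session")
def sim1_condition():
    """The well-powered UDIF condition: S=40, n_s=100, 20% DIF, no impact."""
    return idf.SimDesign(variant="I", groups=40, n_per_group=100, seed=202)


@pytest.fixture(scope="session")
def sim1_path(sim1_condition):
    """One fitted regularization path on the first replication."""
    data, truth = idf.simulate_dataset(sim1_condition, 0)
    spec = sim1_condition.model_spec()
    path = idf.run_path(data, spec, idf.FitConfig())
    return path, truth
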