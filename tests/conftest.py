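import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lipocd as L

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def resv4la_params():
    """1:1 ground truth at the reference condition (pH 7.0, 35 degC, PBS)."""
    return L.BindingParams.one_to_one(6.0, 720.0)


@pytest.fixture
def resv4dha_params():
    """1:2 ground truth at the reference condition."""
    return L.BindingParams.one_to_two(0.001, 17.0, 0.18)


@pytest.fixture
def clean_diagram_1to1(resv4la_params):
    return L.make_diagram(
        L.SyntheticDiagramSpec(
            binding=resv4la_params,
            cd_grid_m=[0.0, 0.001, 0.0025, 0.005, 0.01],
            seed=0,
            noise_cv=0.0,
        )
    )


@pytest.fixture
def clean_diagram_1to2(resv4dha_params):
    return L.make_diagram(
        L.SyntheticDiagramSpec(
            binding=resv4dha_params,
            cd_grid_m=[0.0, 0.005, 0.01, 0.025, 0.05, 0.1],
            seed=0,
            noise_cv=0.0,
        )
    )


@pytest.fixture
def clean_curves(resv4la_params):
    """Noise-free titration batch across five CD levels."""
    curves = []
    for i, cd in enumerate([0.0, 0.001, 0.0025, 0.005, 0.01]):
        spec = L.SyntheticTitrationSpec(
            binding=resv4la_params,
            cd_conc_m=cd,
            seed=10 + i,
            noise_sd=0.0,
            guest="Resv-4'-LA",
        )
        curves.append(L.make_titration(spec))
    return curves
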