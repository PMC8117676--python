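import numpy as np
import pytest

from liposcatter import GeneratorRecipe, NanodiscModel, SLBFitModel
from liposcatter.synthetic_data import simulate_reflectivity, simulate_sans

# dDMPC tail / hDMPC tail SLDs used throughout (1e-6 Å⁻²)
D_TAIL, H_TAIL = 6.93, -0.39


@pytest.fixture(scope="session")
def ddmpc_model():
    """Pristine tail-deuterated DMPC bilayer (representative fit values)."""
    return SLBFitModel(
        head_thickness=9.0, tail_thickness=27.2,
        head_coverage=0.62, tail_coverage=0.96,
        head_sld_material=1.84, tail_sld_material=D_TAIL,
        roughness_common=3.0,
    )


@pytest.fixture(scope="session")
def exchanged_model(ddmpc_model):
    """Same bilayer after 40.4 % of the deuterated tails became hydrogenous."""
    x_h = 0.404
    return ddmpc_model.with_params(
        tail_sld_material=D_TAIL + x_h * (H_TAIL - D_TAIL))


@pytest.fixture(scope="session")
def nr_datasets_noiseless(ddmpc_model):
    return simulate_reflectivity(
        GeneratorRecipe(truth=ddmpc_model, seed=0, rel_noise=0.0))


@pytest.fixture(scope="session")
def nr_datasets_noisy(exchanged_model):
    return simulate_reflectivity(GeneratorRecipe(truth=exchanged_model, seed=42))


@pytest.fixture(scope="session")
def apoe3_disc():
    """Elliptical nanodisc at the fitted ApoE3 geometry."""
    return NanodiscModel(r_minor=42.0, ellipticity=1.4, belt_thickness=11.0,
                         face_thickness=9.0, core_length=28.0)


@pytest.fixture(scope="session")
def sans_datasets_noiseless(apoe3_disc):
    return simulate_sans(
        GeneratorRecipe(truth=apoe3_disc, seed=0, rel_noise=0.0,
                        smearing=False))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211)
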