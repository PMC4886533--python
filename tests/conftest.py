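import numpy as np
import pytest

from dystroquant import (
    ImageSimParams,
    KineticSimParams,
    ProteomeSimParams,
    SERPIN_LIKE_SPEC,
    simulate_image,
    simulate_kinetics,
    simulate_peptide_table,
)


@pytest.fixture(scope="session")
def mixed_scene():
    """20 nuclei; two 3-nucleus myotubes; two mononucleated marker+ cells.

    True differentiation index 8/20 = 0.4, true fusion index 6/8 = 0.75.
    """
    params = ImageSimParams(
        n_nuclei=20, n_myotubes=2, nuclei_per_myotube=3,
        n_mono_myhc_cells=2, myotube_length_px=120, seed=11,
    )
    rgb, gt = simulate_image(params)
    return rgb, gt


@pytest.fixture(scope="session")
def fused_scene():
    """One myotube containing all 10 nuclei: DI = FI = 1."""
    params = ImageSimParams(
        n_nuclei=10, n_myotubes=1, nuclei_per_myotube=10,
        n_mono_myhc_cells=0, frac_touching_pairs=0.0,
        myotube_length_px=200, nucleus_radius_px=5, seed=7,
    )
    return simulate_image(params)


@pytest.fixture(scope="session")
def noiseless_plate():
    return simulate_kinetics(KineticSimParams(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def default_proteome():
    params = ProteomeSimParams(differential_spec=SERPIN_LIKE_SPEC, seed=42)
    return simulate_peptide_table(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
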