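import pytest

from chipdpcr import ChipLayout, PanelConfig, SimulationConfig
from chipdpcr.synthetic_chip import ChannelIntensityModel


@pytest.fixture
def small_layout():
    """A desk-scale chip: 20 x 30 = 600 chambers, same chamber geometry as
    the full device."""
    return ChipLayout(n_channels=2, n_rows=20, chambers_per_row=30)


@pytest.fixture
def panel():
    return PanelConfig()


@pytest.fixture
def noise_free_models(panel):
    """Deterministic intensities: every negative chamber reads exactly
    mu_neg, every positive exactly mu_pos."""
    return {ch: ChannelIntensityModel(sigma_neg=0.0, sigma_pos=0.0)
            for ch in panel.channels}


@pytest.fixture
def noise_free_config(small_layout, panel, noise_free_models):
    return SimulationConfig(
        species_concentrations={"WT": 900.0, "G12D": 100.0},
        seed=11, layout=small_layout, panel=panel,
        intensity_models=noise_free_models, background_noise_sd=0.0,
    )
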