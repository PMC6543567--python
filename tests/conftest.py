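import pytest

import uristrip as u


@pytest.fixture(scope="session")
def fixture_edges() -> u.BinEdges:
    """Bin edges fitted from a noiseless titration of the fixture hue scale."""
    return u.fit_bin_edges(u.make_titration_set(u.DEFAULT_LEVEL_HUES, reps=1, noise_sd_deg=0.0))


@pytest.fixture(scope="session")
def unit_calibration() -> u.CameraCalibration:
    """Identity white balance, reference hue at the fixture negative level."""
    return u.CameraCalibration(
        gains=(1.0, 1.0, 1.0), reference_hue_deg=u.DEFAULT_LEVEL_HUES[0], verified=True
    )


@pytest.fixture()
def config() -> u.AnalysisConfig:
    return u.AnalysisConfig(seed=0)
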