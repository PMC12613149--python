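import dataclasses

import pytest

import timsscreen as ts


@pytest.fixture(scope="session")
def default_config():
    return ts.ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, interference-free single-analyte-friendly scenario."""
    return ts.ScenarioConfig(
        seed=7,
        n_matrix_features=0,
        noise_density=0.0,
        interference_fraction=0.0,
        analyte_absent_fraction=0.0,
        trendline_scatter=0.0,
        intensity_jitter_sd=0.0,
        mz_jitter_ppm_sd=0.0,
    )


@pytest.fixture(scope="session")
def calibration(default_config):
    return ts.fit_ccs_calibration(ts.calibrant_table(default_config))


@pytest.fixture(scope="session")
def small_scenario(default_config):
    """One default scenario: library, spectra, cloud, truth (seed 1)."""
    library, spectra = ts.generate_library(default_config)
    cloud, truth = ts.generate_peak_cloud(library, default_config, spectra=spectra)
    return default_config, library, spectra, cloud, truth


def make_config(**overrides):
    return dataclasses.replace(ts.ScenarioConfig(), **overrides)
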