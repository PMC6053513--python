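import dataclasses

import pytest

import matlith as ml


@pytest.fixture(scope="session")
def lhc_layers():
    layers, _ = ml.default_lhc_params()
    return layers


@pytest.fixture(scope="session")
def noise_free_table(lhc_layers):
    """Four-layer synthetic measurement table with zero noise."""
    _, design = ml.default_lhc_params()
    design = dataclasses.replace(design, machine_sigma=0.0, seed=1)
    return ml.simulate_incubation(lhc_layers, design)


@pytest.fixture(scope="session")
def noisy_table(lhc_layers):
    """Four-layer synthetic table at the study noise level (0.1 per mil)."""
    _, design = ml.default_lhc_params()
    design = dataclasses.replace(design, seed=7)
    return ml.simulate_incubation(lhc_layers, design)


@pytest.fixture(scope="session")
def table1_stations():
    """Station chemistry: stream water above the mat and mat pore waters.

    Columns match the chemistry CSV schema; printed saturation states for
    these stations are 4.62, 3.50, 3.23 and 4.27 in the order listed.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "station": ["upstream", "downstream", "porewater_1cm", "porewater_5cm"],
            "temperature_c": [52.4, 38.1, 38.8, 48.4],
            "ph": [8.34, 8.29, 8.10, 8.30],
            "tco2_mm": [11.91, 11.88, 11.52, 11.59],
            "calcium_mm": [0.55, 0.55, 0.55, 0.55],
        }
    )
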