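import numpy as np
import pandas as pd
import pytest

from rumentox import ExperimentConfig, ToxinKineticParams, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture(scope="session")
def small_dataset(default_config):
    """One complete synthetic experiment at the default study design."""
    return generate_dataset(default_config, seed=42)


@pytest.fixture
def demo_params() -> ToxinKineticParams:
    return ToxinKineticParams(hga0=1.0, hgb0=10.0, k=0.2, l=0.1)


def make_concentration_frame(times, values, analyte="HGA", unit="ng/mL",
                             censored=None, variant="PCM", fermenter="F1"):
    """Minimal tidy concentration table for one analyte on one fermenter."""
    n = len(times)
    return pd.DataFrame(
        {
            "run": ["R1"] * n,
            "fermenter": [fermenter] * n,
            "variant": [variant] * n,
            "medium": ["vital"] * n,
            "time_h": np.asarray(times, dtype=float),
            "analyte": [analyte] * n,
            "value": np.asarray(values, dtype=float),
            "unit": [unit] * n,
            "censored": censored if censored is not None else [False] * n,
        }
    )
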