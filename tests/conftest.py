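import pandas as pd
import pytest

from chemonet import default_screen_config, generate_screen
from chemonet.synthetic import ScreenConfig


@pytest.fixture
def tiny_config() -> ScreenConfig:
    """Three mutants, two drugs, no noise — every call planted."""
    return ScreenConfig(
        drugs={"D1": (1.0, 2.0), "D2": (5.0,)},
        n_mutants=3,
        days=(3, 7),
        planted_calls={
            ("g001", "D1"): "strong",
            ("g002", "D1"): "weak",
            ("g003", "D1"): "transient_resistant",
            ("g001", "D2"): "strong",
        },
        noise_sd=0.0,
        baseline_growth=50.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_screen():
    """The reference 90-mutant x 6-drug design at default noise, seed 0."""
    screen, truth = generate_screen(default_screen_config(seed=0))
    return screen, truth


def make_screen(rows) -> pd.DataFrame:
    """Build a screen table from (strain, drug, conc, day, growth) tuples."""
    return pd.DataFrame(
        rows, columns=["strain", "drug", "concentration", "day", "growth"]
    )
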