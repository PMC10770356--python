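import numpy as np
import pandas as pd
import pytest

from phostrend import GROUPS, IntensityMatrix, SimulationConfig, simulate_dataset


def make_matrix(rows: dict[str, list[float]], reps: int = 2, level="protein",
                sites: pd.DataFrame | None = None) -> IntensityMatrix:
    """Tiny matrix builder: each row lists reps values per group in C,CT,M,MT order."""
    samples = [f"{g}{r}" for g in GROUPS for r in range(1, reps + 1)]
    groups = pd.Series({s: s.rstrip("0123456789") for s in samples})
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return IntensityMatrix(values, groups, level=level, sites=sites)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic dataset at the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(
        n_proteins=40,
        n_sites=20,
        noise_sd=0.0,
        missing_rate=0.0,
        seed=3,
    )
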