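import numpy as np
import pandas as pd
import pytest

from loopmotif import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def ramp_study_clean():
    """Zero-noise study with a monotone response ramp (imputation is exact)."""
    cfg = SimulationConfig(noise_sd=0.0, peak_time_h=168.0, seed=42)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def peaked_study_noisy():
    """Default-shaped study: peaked response at 24 h, noise 0.3 log2 units."""
    return simulate_study(SimulationConfig(seed=7))


def pairs_frame(rows):
    """Build a typed pair table from (source, target, edge_class) tuples."""
    df = pd.DataFrame(rows, columns=["source_id", "target_id", "edge_class"])
    df["provenance"] = [frozenset(["test"])] * len(df)
    return df
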