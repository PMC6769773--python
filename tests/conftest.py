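import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from plasmir import CountMatrix, PanelDefinition, SimulationConfig, generate_counts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """Hand-sized matrix: 3 endogenous, 5 negative, 2 positive, 2 housekeeping
    probes over two samples in different cohorts."""
    probes = ["miR-a", "miR-b", "miR-c", "N1", "N2", "N3", "N4", "N5", "P1", "P2", "H1", "H2"]
    classes = ["endogenous"] * 3 + ["negative"] * 5 + ["positive"] * 2 + ["housekeeping"] * 2
    counts = pd.DataFrame(
        {
            "s1": [100.0, 5.0, 40.0, 1, 2, 3, 4, 5, 50.0, 200.0, 50.0, 50.0],
            "s2": [80.0, 60.0, 40.0, 1, 2, 3, 4, 5, 200.0, 800.0, 200.0, 200.0],
        },
        index=probes,
    )
    return CountMatrix(
        counts=counts,
        probe_class=pd.Series(classes, index=probes),
        cohorts=pd.Series(["Control", "FIGO_I"], index=["s1", "s2"]),
    )


@pytest.fixture
def small_panel() -> PanelDefinition:
    """Down-scaled panel (40 endogenous probes) for fast end-to-end runs."""
    return PanelDefinition(
        endogenous_ids=[f"m{i:02d}" for i in range(40)],
        negative_ids=[f"N{i}" for i in range(6)],
        positive_ids=[f"P{i}" for i in range(6)],
        housekeeping_ids=[f"H{i}" for i in range(10)],
    )


def planted_config(seed: int, effect: float = 2.0, **kw) -> SimulationConfig:
    """Study-design config planting 8 probes per miRNA group on the default
    798-probe panel."""
    ids = PanelDefinition().endogenous_ids
    return SimulationConfig(
        planted_group1=[(p, effect) for p in ids[:8]],
        planted_group2=[(p, effect) for p in ids[8:16]],
        planted_group3=[(p, effect) for p in ids[16:24]],
        seed=seed,
        **kw,
    )


@pytest.fixture
def seeded_run():
    cfg = planted_config(seed=7)
    cm, truth = generate_counts(cfg)
    return cfg, cm, truth
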