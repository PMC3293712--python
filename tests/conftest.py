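"""Shared fixtures: small hand-built designs and a cached simulated study."""

import numpy as np
import pandas as pd
import pytest

from poolgwas.design import PoolDesign
from poolgwas.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def design_2x2x2() -> PoolDesign:
    """Minimal balanced design: 2 groups x 2 pools x 2 replicates."""
    return PoolDesign(
        groups=("case", "control"),
        pool_to_group={"cp1": "case", "cp2": "case", "kp1": "control", "kp2": "control"},
        replicate_to_pool={
            "cp1_r1": "cp1", "cp1_r2": "cp1",
            "cp2_r1": "cp2", "cp2_r2": "cp2",
            "kp1_r1": "kp1", "kp1_r2": "kp1",
            "kp2_r1": "kp2", "kp2_r2": "kp2",
        },
    )


def make_balanced_design(n_pools: int = 6, n_reps: int = 3) -> PoolDesign:
    pool_to_group, replicate_to_pool = {}, {}
    for group in ("case", "control"):
        for j in range(n_pools):
            pool = f"{group}_p{j + 1}"
            pool_to_group[pool] = group
            for r in range(n_reps):
                replicate_to_pool[f"{pool}_r{r + 1}"] = pool
    return PoolDesign(("case", "control"), pool_to_group, replicate_to_pool)


@pytest.fixture(scope="session")
def design_2x6x3() -> PoolDesign:
    return make_balanced_design(6, 3)


def freq_frame(design: PoolDesign, values: dict[str, float], marker: str = "rs1") -> pd.DataFrame:
    """One-marker long frequency table from {replicate_id: freq}."""
    return pd.DataFrame(
        {
            "marker_id": marker,
            "replicate_id": list(values),
            "method": "U",
            "freq": list(values.values()),
            "valid": True,
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A 120-marker default-condition study with 6 injected effect markers."""
    config = SimulationConfig(
        n_markers=120, n_effect_markers=6, effect_size=0.15, seed=0
    )
    return generate_study(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
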