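import numpy as np
import pytest

from paleomorph.landmark_io import LandmarkConfiguration, ShapeDataset
from paleomorph.synthetic_data import GuildSpec, RadiationScenario


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_dataset(rng, n=3, n_fixed=7, n_curve=38, scale=1.0):
    """Small homogeneous dataset with one digitized curve per specimen."""
    configs = []
    for i in range(n):
        pts = rng.uniform(0, 100, size=(n_fixed + n_curve, 2)) * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"spec_{i}",
                points=pts,
                n_fixed=n_fixed,
                curves=[(n_fixed, n_fixed + n_curve)],
            )
        )
    return ShapeDataset(configs)


@pytest.fixture
def tiny_dataset(rng):
    return random_dataset(rng)


def small_scenario(seed=None, **overrides):
    """Scaled-down radiation (6 guilds, ~150 specimens) for fast unit tests."""
    guilds = [
        GuildSpec("generalist", 16.5, 0.0),
        GuildSpec("demersal-insectivore", 15.4, 0.04),
        GuildSpec("pelagic-zooplanktivore", 14.7, 0.05),
        GuildSpec("insect-picker", 14.4, 0.06),
        GuildSpec("piscivore", 13.8, 0.08),
        GuildSpec("oral-snail-crusher", 4.0, 0.10),
    ]
    defaults = dict(
        guilds=guilds,
        n_modern=60,
        fossil_bin_counts={
            "early-wetland": 6,
            "wetland": 20,
            "shallow-lake": 60,
            "deep-lake": 30,
        },
        shallow_age_split=None,
        seed=seed,
        name="small-test",
    )
    defaults.update(overrides)
    return RadiationScenario(**defaults)
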