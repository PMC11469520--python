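import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from qpharm.features import FeatureClass, PharmFeature, Pharmacophore
from qpharm.rl import PharmEnv, QTrainConfig, library_reward, train_q
from qpharm.synth import (SyntheticLibrarySpec, SyntheticPocketSpec,
                          make_library, make_pocket, make_unique_optimum_task)


@pytest.fixture(scope="session")
def pocket():
    """One 4-site synthetic pocket with its confidence oracle."""
    return make_pocket(SyntheticPocketSpec(n_sites=4, seed=7))


@pytest.fixture(scope="session")
def planted_pharm():
    return Pharmacophore([
        PharmFeature([0.0, 0.0, 0.0], FeatureClass.HydrogenAcceptor),
        PharmFeature([3.0, 0.0, 0.0], FeatureClass.Aromatic),
        PharmFeature([0.0, 3.5, 0.0], FeatureClass.Hydrophobic),
        PharmFeature([2.0, 2.0, 2.5], FeatureClass.PositiveIon),
    ], name="planted")


@pytest.fixture(scope="session")
def planted_library(planted_pharm):
    """20 verified actives / 80 verified decoys around the planted model."""
    return make_library(SyntheticLibrarySpec(planted_pharm, n_actives=20,
                                             n_decoys=80, seed=3))


@pytest.fixture(scope="session")
def unique_task():
    """8 candidate features with a unique perfect 3-subset."""
    return make_unique_optimum_task(8, seed=11)


@pytest.fixture(scope="session")
def trained_policy(unique_task):
    """A single Q-network trained for 300 episodes on the planted task."""
    env = PharmEnv(unique_task.features, unique_task.protein,
                   library_reward(unique_task.library))
    cfg = QTrainConfig(episodes=300, ensemble_size=1, seed=19, gamma=0.9)
    result = train_q(env, cfg)
    return unique_task, env, result
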