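import pytest

from archmatnet import ModelConfig, init_world


def quiet_config(**overrides) -> ModelConfig:
    """A configuration in which nothing stochastic ever happens."""
    base = dict(
        nTicks=10, nBands=2, campPopulation=4,
        pEnvChange=0.0, envMode="mutating",
        aggregationFreq=0.0, aggregationDuration=2,
        pHunting=0.0, huntingGroupSize=3,
        pVisiting=0.0, pNewAlliance=0.0, maximumAlliesN=5,
        pMigration=0.0, genderedMigration=False,
        pTrading=0.0, transmissionRate=0.0, learningMethod="prestige",
        pLuckyLeap=0.0, pNewVariant=0.0, pNewObject=0.0, pLoss=0.0,
        potteryPrestige="random_values", uniqueTraits=False,
        visibility=False, pDropPot=0.0, pDropPoint=0.0,
        migrationOnsetTick=1000, snapshotInterval=1000, randomSeed=7,
    )
    base.update(overrides)
    return ModelConfig(**base)


def small_config(**overrides) -> ModelConfig:
    """A small but fully active configuration for fast integration runs."""
    base = dict(nTicks=200, nBands=2, campPopulation=4, huntingGroupSize=3,
                randomSeed=11)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def quiet_world():
    return init_world(quiet_config())


@pytest.fixture
def small_world():
    return init_world(small_config())
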