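import pytest

from hbocprio.synthetic_data import (
    PlantedVariant,
    ReplicationConfig,
    ReplicationPlant,
    SimulationConfig,
    simulate_cohort,
    simulate_replication_cohort,
)

PLANTED_GENES = ("RISK1", "RISK2", "RISK3")


def clean_discovery_config(seed: int = 11, **overrides) -> SimulationConfig:
    """Study-scale cohort (17 families / 52 sequenced) with three planted
    fully penetrant LoF variants and no qualifying LoF background: rare
    background strata carry non-LoF consequences and zero damaging
    predictor verdicts, so planted truths are the only qualifying signal."""
    kwargs = dict(
        planted_risk=[PlantedVariant(gene=g) for g in PLANTED_GENES],
        rare_lof_background=False,
        background_damaging_rate=0.0,
        random_seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def clean_bundle():
    return simulate_cohort(clean_discovery_config())


@pytest.fixture(scope="session")
def replication_bundle(clean_bundle):
    cfg = ReplicationConfig(
        rare_lof_background=False,
        background_damaging_rate=0.0,
        plants=[ReplicationPlant(gene="RISK1"), ReplicationPlant(gene="RISK3")],
        identical_variants=[tuple(t["key"]) for t in clean_bundle.truth["planted"][:1]],
        random_seed=23,
    )
    return simulate_replication_cohort(cfg, clean_bundle.records)
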