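import pytest
from hypothesis import HealthCheck, settings

from retap import (
    MetabolicModel,
    MetaboliteRecord,
    ReactionRecord,
    ToyModelSpec,
    build_branched_toy,
    enforced_production_scan,
    set_carbon_source,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """Minimal linear pathway: EX_A ⇒ A --R_AP--> P ⇒ EX_P."""
    return MetabolicModel(
        model_id="chain",
        metabolites=(MetaboliteRecord("A_c", "c"), MetaboliteRecord("P_c", "c")),
        reactions=(
            ReactionRecord("EX_A", "", {"A_c": -1.0}, -uptake, 1000.0),
            ReactionRecord("R_AP", "", {"A_c": -1.0, "P_c": 1.0}, 0.0, 1000.0),
            ReactionRecord("EX_P", "", {"P_c": -1.0}, 0.0, 1000.0),
        ),
        genes=(),
        objective_reaction="EX_P",
    )


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def toy():
    """Default branched toy model (carbon already set) and its ground truth."""
    model, truth = build_branched_toy(ToyModelSpec())
    return set_carbon_source(model, truth.carbon_id, 10.0), truth


@pytest.fixture(scope="session")
def toy_scan(toy):
    """Default enforced-production scan of the branched toy (10 fractions,
    10% biomass floor)."""
    model, truth = toy
    return enforced_production_scan(
        model, truth.product_id, truth.biomass_id, truth.carbon_id
    )
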