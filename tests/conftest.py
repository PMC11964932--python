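import pytest

from metaorg import assembly as asm
from metaorg import simulate as sim
from metaorg.network import MetabolicModel, Metabolite, Reaction

BBB = {"glc", "o2", "aa", "co2", "lac"}


@pytest.fixture(scope="session")
def bundle():
    return sim.make_fixture_bundle(1)


@pytest.fixture(scope="session")
def metamodel(bundle):
    mm = asm.assemble_metamodel(bundle.tissue_models, bundle.microbiome,
                                bbb=BBB)
    return asm.apply_diet(mm, bundle.diet)


@pytest.fixture
def chain_model():
    """Linear chain: uptake (ub 10) -> conversion -> export, 1:1."""
    return MetabolicModel(
        [Metabolite("A"), Metabolite("B")],
        [
            Reaction("U", {"A": 1}, 0, 10, provenance="exchange"),
            Reaction("C", {"A": -1, "B": 1}, 0, 1000, provenance="colon"),
            Reaction("E", {"B": -1}, 0, 1000, provenance="exchange"),
        ],
        objective="E",
    )
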