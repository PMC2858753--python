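import pytest

from coremetnet.data_model import Reaction
from coremetnet.graph_build import build_graph
from coremetnet.synthetic_data import SyntheticStudyTruth, generate_study


def make_reaction(rid, educts, products, pairs, ec=None, spontaneous=False, **kw):
    """Shorthand constructor for hand-built reactions in tests."""
    return Reaction(
        reaction_id=rid,
        ec_numbers=frozenset(ec or ([] if spontaneous else [f"1.1.1.{rid}"])),
        educts=frozenset(educts),
        products=frozenset(products),
        main_pairs=frozenset(pairs),
        spontaneous=spontaneous,
        **kw,
    )


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default scale (seed fixed)."""
    return generate_study(SyntheticStudyTruth(seed=1))


@pytest.fixture(scope="session")
def reference_graph(default_study):
    return build_graph(default_study.reactions, "ALL", label="reference")


@pytest.fixture()
def chain_reactions():
    """Three reactions chaining A-B, B-C, C-D (plus ATP on the first)."""
    return [
        make_reaction("R1", {"A", "ATP"}, {"B", "ADP"}, {("A", "B")}),
        make_reaction("R2", {"B"}, {"C"}, {("B", "C")}),
        make_reaction("R3", {"C"}, {"D"}, {("C", "D")}),
    ]
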