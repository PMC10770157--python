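import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from tamboor.model import MetabolicModel, Metabolite, Reaction


def chain_model(length: int = 3, uptake: float = 10.0) -> MetabolicModel:
    """Linear toy: S --R1..Rn--> M with uptake and secretion exchanges."""
    mets = [Metabolite("S"), Metabolite("M")]
    rxns = []
    prev = "S"
    for i in range(1, length + 1):
        nxt = "M" if i == length else f"I{i}"
        if nxt != "M":
            mets.append(Metabolite(nxt))
        rxns.append(Reaction(id=f"R{i}", stoichiometry={prev: -1.0, nxt: 1.0}, gpr=f"g{i}"))
        prev = nxt
    rxns.append(Reaction(id="EX_S", stoichiometry={"S": -1.0}, lower_bound=-uptake))
    rxns.append(Reaction(id="EX_M", stoichiometry={"M": -1.0}))
    m = MetabolicModel(metabolites=mets, reactions=rxns, id="chain")
    m.validate()
    return m


@pytest.fixture
def chain3() -> MetabolicModel:
    return chain_model(3)


def unit_weights(irr) -> dict:
    return {r: 1.0 for r in irr.reaction_ids}
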