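import numpy as np
import pytest

from efmsig.gpr import BoolOp, GeneRef
from efmsig.simulate import glycolysis_tca_network


@pytest.fixture(scope="session")
def glyc_tca():
    return glycolysis_tca_network()


@pytest.fixture(scope="session")
def glyc_tca_efms(glyc_tca):
    from efmsig.efm import enumerate_efms
    return enumerate_efms(glyc_tca)


# supports of the three toy-network EFMs: anaerobic glycolysis, aerobic
# glycolysis via the TCA cycle, TCA cycle fed by acetate
GLYC_TCA_SUPPORTS = {
    frozenset({"R_glyc", "R_ldh"}),
    frozenset({"R_glyc", "R_pdh", "R_cs", "R_tca"}),
    frozenset({"R_ack", "R_cs", "R_tca"}),
}


def random_gpr_tree(rng: np.random.Generator, genes: list[str], depth: int):
    """Random GPR expression tree of at most the given depth."""
    if depth == 0 or rng.random() < 0.3:
        return GeneRef(str(rng.choice(genes)))
    op = "and" if rng.random() < 0.5 else "or"
    return BoolOp(op, random_gpr_tree(rng, genes, depth - 1),
                  random_gpr_tree(rng, genes, depth - 1))
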