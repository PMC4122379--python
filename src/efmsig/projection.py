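"""Projection of three-level gene states onto reactions through GPR rules.

Each reaction inherits the value of its GPR rule evaluated over the gene
states with and = min and or = max on the order -1 < 0 < +1.  Genes
without expression evidence count as 0 (absence of evidence is not low
expression), and reactions without any GPR are 0 and flagged so that
downstream enrichment can exclude them from the evidence universe.

Note that negating every gene state does *not* necessarily negate the
reaction states: or(+1, -1) = +1 and or(-1, +1) = +1, so an up-vs-down
label swap that is an exact mirror at gene level generally is not at
reaction level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .expression import GeneStateVector
from .gpr import evaluate_gpr, genes_of
from .network import MetabolicNetwork

logger = logging.getLogger(__name__)

__all__ = ["ReactionStateVector", "evaluate_gpr", "project_states"]


@dataclass
class ReactionStateVector:
    """Per-scenario {-1, 0, +1} reaction calls; ``no_gpr`` lists reactions
    with no rule (always 0)."""

    scenario: str
    states: dict[str, int]
    no_gpr: frozenset[str] = frozenset()

    def __post_init__(self):
        bad = {r: s for r, s in self.states.items() if s not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"states outside {{-1,0,+1}}: {bad}")

    def counts(self) -> tuple[int, int, int]:
        """(n_plus, n_zero, n_minus)."""
        vals = list(self.states.values())
        return vals.count(1), vals.count(0), vals.count(-1)


def project_states(net: MetabolicNetwork,
                   gene_states: GeneStateVector) -> ReactionStateVector:
    """Evaluate every reaction's GPR over the gene states.

    Reactions without a GPR get state 0 and are recorded in ``no_gpr``.
    Gene ids present in rules but absent from the state vector are
    absorbed as 0, with a logged count.
    """
    states: dict[str, int] = {}
    no_gpr: set[str] = set()
    missing: set[str] = set()
    for r in net.reactions:
        if r.gpr is None:
            states[r.id] = 0
            no_gpr.add(r.id)
            continue
        missing |= genes_of(r.gpr) - gene_states.states.keys()
        states[r.id] = evaluate_gpr(r.gpr, gene_states.states)
    if missing:
        logger.info("scenario %s: %d GPR gene(s) without expression evidence "
                    "treated as state 0", gene_states.scenario, len(missing))
    return ReactionStateVector(scenario=gene_states.scenario, states=states,
                               no_gpr=frozenset(no_gpr))


def reaction_states_to_tsv(vector: ReactionStateVector) -> str:
    lines = ["reaction\tstate\thas_gpr"]
    for r, s in vector.states.items():
        lines.append(f"{r}\t{s}\t{int(r not in vector.no_gpr)}")
    return "\n".join(lines) + "\n"
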