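"""Synthetic inputs: toy networks and planted-signal expression data.

This module generates everything the pipeline consumes, with recorded
ground truth so recovery can be tested: the glycolysis/TCA toy network
(three EFMs: anaerobic glycolysis, aerobic glycolysis via the TCA cycle,
and the TCA cycle fed by acetate), random small networks for property
tests, and probe-level expression matrices in which the genes of chosen
"planted" EFMs draw from the active intensity component while everything
else stays inactive.

The intensity model is bimodal on the log2 scale — an inactive component
(default N(5, 1)) and an active component (default N(11, 1)), the minimal
model under which present/absent calling is well-posed — plus i.i.d.
per-probe-per-sample measurement noise.  Planted genes are additionally
shifted by ``effect_size`` log2 units above the active mean in the groups
where their EFM is planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd

from .efm import EFMCollection
from .expression import ExpressionMatrix
from .gpr import genes_of, parse_gpr
from .network import MetabolicNetwork, Metabolite, Reaction


def glycolysis_tca_network() -> MetabolicNetwork:
    """The glycolysis/TCA toy network with exactly three EFMs.

    Boundary species: glucose (D-Glc), acetate (Ac) as inputs, lactate
    (D-Lac) and CO2 as outputs; internal: pyruvate, acetyl-CoA, citrate,
    oxaloacetate.  Six irreversible lumped reactions, each catalyzed by
    its own single-gene GPR.
    """
    def ext(mid, name):
        return Metabolite(mid, name=name, compartment="e", external=True)

    def cyt(mid, name):
        return Metabolite(mid, name=name, compartment="c", external=False)

    mets = [
        ext("D-Glc", "glucose"), ext("Ac", "acetate"),
        ext("D-Lac", "lactate"), ext("CO2", "carbon dioxide"),
        cyt("Pyr", "pyruvate"), cyt("AcCoA", "acetyl-CoA"),
        cyt("Cit", "citrate"), cyt("OAA", "oxaloacetate"),
    ]
    one, two = Fraction(1), Fraction(2)
    rxns = [
        Reaction("R_glyc", {"D-Glc": -one, "Pyr": two}, gpr=parse_gpr("g_glyc")),
        Reaction("R_ldh", {"Pyr": -one, "D-Lac": one}, gpr=parse_gpr("g_ldh")),
        Reaction("R_pdh", {"Pyr": -one, "AcCoA": one, "CO2": one},
                 gpr=parse_gpr("g_pdh")),
        Reaction("R_ack", {"Ac": -one, "AcCoA": one}, gpr=parse_gpr("g_ack")),
        Reaction("R_cs", {"AcCoA": -one, "OAA": -one, "Cit": one},
                 gpr=parse_gpr("g_cs")),
        Reaction("R_tca", {"Cit": -one, "OAA": one, "CO2": two},
                 gpr=parse_gpr("g_tca")),
    ]
    return MetabolicNetwork(mets, rxns)


def random_network(n_internal: int, n_reactions: int, rev_prob: float = 0.2,
                   seed: int = 0, n_external: int = 2) -> MetabolicNetwork:
    """A random connected network for property tests.

    A backbone chain boundary → internals → boundary guarantees
    connectivity and at least one pathway; remaining reactions are random
    unit-coefficient conversions.  Every reaction carries a 1- or 2-gene
    GPR.  Deterministic for a given seed.
    """
    if n_external < 2:
        raise ValueError("need at least 2 external metabolites")
    min_rxns = n_internal + 1 if n_internal > 0 else 1
    if n_reactions < min_rxns:
        raise ValueError(f"{n_reactions} reactions cannot span {n_internal} "
                         f"internal metabolites (need >= {min_rxns})")
    rng = np.random.default_rng(seed)
    ext = [Metabolite(f"X{i}", compartment="e", external=True)
           for i in range(n_external)]
    internal = [Metabolite(f"M{i}", compartment="c") for i in range(n_internal)]
    mets = ext + internal
    all_ids = [m.id for m in mets]
    one = Fraction(1)

    rxns: list[Reaction] = []

    def add(sub: str, prod: str):
        i = len(rxns)
        n_genes = int(rng.integers(1, 3))
        if n_genes == 1:
            gpr = parse_gpr(f"gr{i}a")
        else:
            op = "and" if rng.random() < 0.5 else "or"
            gpr = parse_gpr(f"gr{i}a {op} gr{i}b")
        rxns.append(Reaction(f"R{i}", {sub: -one, prod: one},
                             reversible=bool(rng.random() < rev_prob), gpr=gpr))

    # backbone chain through every internal metabolite
    chain = ["X0"] + [m.id for m in internal] + ["X1"]
    for a, b in zip(chain, chain[1:]):
        add(a, b)
    while len(rxns) < n_reactions:
        a, b = rng.choice(all_ids, size=2, replace=False)
        add(str(a), str(b))
    net = MetabolicNetwork(mets, rxns)

    g = nx.Graph()
    for r in net.reactions:
        ids = list(r.stoichiometry)
        g.add_edges_from(zip(ids, ids[1:]))
    assert nx.is_connected(g) if g.number_of_nodes() else True
    return net


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class SimulationConfig:
    """Study conditions for the expression generator.

    Defaults emulate a small two-cancer-subtypes-plus-control design:
    three groups of 10 samples, 1–3 probes per gene, planted effect of
    2 log2 units over the active component, measurement noise sd 0.5.
    """

    seed: int = 0
    n_genes: int | None = None  # None: GPR genes + 25% decoys (min 10)
    probes_per_gene: tuple[int, int] = (1, 3)
    groups: dict[str, int] = field(
        default_factory=lambda: {"AD": 10, "SQ": 10, "CN": 10})
    planted_efms: dict[str, frozenset[str]] = field(default_factory=dict)
    effect_size: float = 2.0
    noise_sd: float = 0.5
    inactive_mean: float = 5.0
    inactive_sd: float = 1.0
    active_mean: float = 11.0
    active_sd: float = 1.0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.inactive_mean >= self.active_mean:
            raise ValueError("components must be ordered: inactive mean < active mean")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs >= 2 samples")
        lo, hi = self.probes_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("probes_per_gene must be a range with 1 <= lo <= hi")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    gene_states: dict[str, dict[str, int]]  # group → gene → {-1,+1}
    planted_efms: dict[str, frozenset[str]]
    probe_active: dict[str, pd.DataFrame]  # group → probes × samples bool


def simulate_expression(net: MetabolicNetwork, efms: EFMCollection,
                        config: SimulationConfig,
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Probe-level expression with planted EFM signal.

    In each group, genes appearing in the GPR rules of the group's
    planted EFMs' support reactions draw from the active component
    shifted up by ``effect_size``; all other genes (GPR or decoy) draw
    from the inactive component.  Fully reproducible for a fixed seed.
    """
    known = set(efms.ids)
    for grp, planted in config.planted_efms.items():
        missing = set(planted) - known
        if missing:
            raise ValueError(f"group {grp!r} plants unknown EFM(s): {sorted(missing)}")
        if grp not in config.groups:
            raise ValueError(f"planted group {grp!r} not in the group plan")
    if config.effect_size == 0 and config.planted_efms:
        import logging
        logging.getLogger(__name__).warning(
            "effect_size = 0: planted signal only distinguishable through "
            "component membership, not shift")

    rng = np.random.default_rng(config.seed)
    gpr_genes = sorted(net.genes())
    n_genes = config.n_genes
    if n_genes is None:
        n_genes = len(gpr_genes) + max(10, len(gpr_genes) // 4)
    if n_genes < len(gpr_genes):
        raise ValueError(f"n_genes={n_genes} below the {len(gpr_genes)} GPR genes")
    decoys = [f"decoy{i:04d}" for i in range(n_genes - len(gpr_genes))]
    genes = gpr_genes + decoys

    lo, hi = config.probes_per_gene
    probe_to_gene: dict[str, str] = {}
    for g in genes:
        for j in range(int(rng.integers(lo, hi + 1))):
            probe_to_gene[f"{g}__p{j}"] = g
    probes = list(probe_to_gene)

    rxn_by_id = {r.id: r for r in net.reactions}
    active_genes: dict[str, frozenset[str]] = {}
    for grp in config.groups:
        planted = config.planted_efms.get(grp, frozenset())
        acc: set[str] = set()
        for eid in planted:
            for rid in efms[eid].support:
                r = rxn_by_id.get(rid)
                if r is not None and r.gpr is not None:
                    acc |= genes_of(r.gpr)
        active_genes[grp] = frozenset(acc)

    samples, sample_groups = [], {}
    for grp, n in config.groups.items():
        for j in range(n):
            sid = f"{grp}_s{j:02d}"
            samples.append(sid)
            sample_groups[sid] = grp

    values = np.empty((len(probes), len(samples)))
    truth_active: dict[str, np.ndarray] = {
        grp: np.zeros((len(probes), n), dtype=bool)
        for grp, n in config.groups.items()}
    col = 0
    for grp, n in config.groups.items():
        hot = active_genes[grp]
        is_hot = np.array([probe_to_gene[p] in hot for p in probes])
        mean = np.where(is_hot, config.active_mean + config.effect_size,
                        config.inactive_mean)
        sd = np.where(is_hot, config.active_sd, config.inactive_sd)
        block = rng.normal(mean[:, None], sd[:, None], size=(len(probes), n))
        if config.noise_sd > 0:
            block = block + rng.normal(0.0, config.noise_sd, size=block.shape)
        values[:, col:col + n] = block
        truth_active[grp][:] = is_hot[:, None]
        col += n

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=samples),
        probe_to_gene, sample_groups)
    gene_states = {
        grp: {g: (1 if g in active_genes[grp] else -1) for g in genes}
        for grp in config.groups}
    probe_active = {
        grp: pd.DataFrame(truth_active[grp], index=probes,
                          columns=[s for s in samples if sample_groups[s] == grp])
        for grp in config.groups}
    truth = GroundTruth(gene_states=gene_states,
                        planted_efms={g: frozenset(v) for g, v in
                                      config.planted_efms.items()},
                        probe_active=probe_active)
    return expr, truth


def simulate_two_group(n_genes: int, n_planted: int, shift: float, sd: float,
                       n_per_group: int = 10, seed: int = 0,
                       groups: tuple[str, str] = ("A", "B"),
                       baseline: float = 8.0,
                       ) -> tuple[ExpressionMatrix, list[str]]:
    """Flat two-group matrix with a planted mean shift in the first group.

    One probe per gene around a common baseline; the first ``n_planted``
    genes are shifted up by ``shift`` log2 units in ``groups[0]``.
    Returns the matrix and the planted gene ids.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    probes = {f"{g}__p0": g for g in genes}
    samples = [f"{grp}_s{j:02d}" for grp in groups for j in range(n_per_group)]
    sample_groups = {s: s.split("_s")[0] for s in samples}
    values = rng.normal(baseline, sd, size=(n_genes, 2 * n_per_group))
    values[:n_planted, :n_per_group] += shift
    expr = ExpressionMatrix(pd.DataFrame(values, index=list(probes),
                                         columns=samples),
                            probes, sample_groups)
    return expr, genes[:n_planted]


def parallel_pathway_network(n_pathways: int, length: int = 3,
                             ) -> tuple[MetabolicNetwork, EFMCollection]:
    """``n_pathways`` disjoint linear pathways, each its own EFM.

    Pathway i converts boundary metabolite in_i to out_i through
    ``length`` irreversible reactions over ``length - 1`` internal
    intermediates; every reaction has a distinct single-gene GPR.  The
    EFM collection (one unit-flux mode per pathway) is returned alongside,
    constructed directly — the structure makes it exhaustive by design.
    Useful as a scoring/prominence testbed with a known EFM↔metabolite map.
    """
    from .efm import FluxMode
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    modes = []
    one = Fraction(1)
    for i in range(n_pathways):
        chain = [f"in{i}"] + [f"mid{i}_{j}" for j in range(length - 1)] + [f"out{i}"]
        mets.append(Metabolite(chain[0], compartment="e", external=True))
        mets += [Metabolite(c, compartment="c") for c in chain[1:-1]]
        mets.append(Metabolite(chain[-1], compartment="e", external=True))
        flux = {}
        for j, (a, b) in enumerate(zip(chain, chain[1:])):
            rid = f"P{i}_{j}"
            rxns.append(Reaction(rid, {a: -one, b: one},
                                 gpr=parse_gpr(f"gene_{rid}")))
            flux[rid] = one
        modes.append(FluxMode(id=f"EFM{i + 1}", flux=flux))
    net = MetabolicNetwork(mets, rxns)
    return net, EFMCollection(modes, net.reaction_ids, provenance="enumerated")
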