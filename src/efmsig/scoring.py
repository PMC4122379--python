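"""Characteristic / differential / prominent EFM selection.

An EFM is scored against a scenario's reaction states by a one-sided
hypergeometric enrichment test: drawing the EFM's GPR-covered support
(size n) from the N GPR-covered reactions of the collection, of which K
are at state +1, what is the probability of seeing at least the observed
number of +1 reactions?  An EFM whose support carries more than a small
fraction of -1 reactions (``tau_low``, default 10%) is disqualified
outright: a pathway is not a candidate signature if part of it is
switched off.  Storey q-values over the non-disqualified scores control
the FDR, and EFMs with q below the threshold (default 20%) are selected.

"Characteristic" selections use absolute (+1 = highly expressed) states,
"differential" selections use up/down states between two conditions, and
"prominent" EFMs are those selected in both arms at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .efm import EFMCollection, FluxMode
from .expression import storey_qvalues
from .projection import ReactionStateVector

logger = logging.getLogger(__name__)

DEFAULT_TAU_LOW = 0.1
DEFAULT_EFM_FDR = 0.20


@dataclass
class EFMScore:
    efm_id: str
    scenario: str
    n_support: int          # GPR-covered support size
    n_high_in_efm: int      # +1 reactions in covered support
    n_low_in_efm: int       # -1 reactions in covered support
    background: tuple[int, int]  # (N covered reactions, K at +1)
    p_value: float
    q_value: float = float("nan")
    disqualified: bool = False
    reason: str = ""


@dataclass
class ScenarioSelection:
    scenario: str
    selected: set[str]
    fdr_threshold: float
    mode: str  # "characteristic" | "differential"
    scores: list[EFMScore] = field(default_factory=list)

    @property
    def scored_ids(self) -> frozenset[str]:
        return frozenset(s.efm_id for s in self.scores)


def gpr_covered_background(collection: EFMCollection,
                           rstates: ReactionStateVector) -> tuple[frozenset[str], int]:
    """Evidence universe for enrichment: GPR-covered reactions appearing in
    at least one EFM of the collection.  Returns (universe, K at +1)."""
    in_some_efm: set[str] = set()
    for m in collection:
        in_some_efm |= m.support
    universe = frozenset(r for r in in_some_efm
                         if r in rstates.states and r not in rstates.no_gpr)
    k = sum(1 for r in universe if rstates.states[r] == 1)
    return universe, k


def score_efm(efm: FluxMode, rstates: ReactionStateVector,
              tau_low: float = DEFAULT_TAU_LOW,
              background: tuple[frozenset[str], int] | None = None) -> EFMScore:
    """Hypergeometric enrichment score of one EFM in one scenario.

    ``background`` is (universe of GPR-covered reactions, count at +1); by
    default it is every GPR-covered reaction of the state vector, which
    :func:`score_collection` overrides with the collection-restricted
    universe.  p = P[X >= n_high] for X ~ Hypergeom(N, K, n_support).
    Disqualified when the covered support is empty ("no evidence") or its
    -1 fraction exceeds ``tau_low``.
    """
    if background is None:
        universe = frozenset(r for r in rstates.states if r not in rstates.no_gpr)
        background = (universe, sum(1 for r in universe if rstates.states[r] == 1))
    universe, K = background
    covered = [r for r in efm.support if r in universe]
    n = len(covered)
    N = len(universe)
    n_high = sum(1 for r in covered if rstates.states[r] == 1)
    n_low = sum(1 for r in covered if rstates.states[r] == -1)
    if n == 0:
        return EFMScore(efm.id, rstates.scenario, 0, 0, 0, (N, K), 1.0,
                        disqualified=True, reason="no evidence")
    p = float(hypergeom.sf(n_high - 1, N, K, n))
    score = EFMScore(efm.id, rstates.scenario, n, n_high, n_low, (N, K), p)
    if n_low / n > tau_low:
        score.disqualified = True
        score.reason = f"low fraction {n_low}/{n} exceeds tau_low={tau_low}"
    return score


def score_collection(collection: EFMCollection, rstates: ReactionStateVector,
                     tau_low: float = DEFAULT_TAU_LOW) -> list[EFMScore]:
    """Score every EFM of a collection against one scenario."""
    background = gpr_covered_background(collection, rstates)
    return [score_efm(m, rstates, tau_low=tau_low, background=background)
            for m in collection]


def select_efms(scores: Sequence[EFMScore],
                fdr_threshold: float = DEFAULT_EFM_FDR,
                mode: str = "characteristic") -> ScenarioSelection:
    """FDR-controlled selection: q-values over non-disqualified scores,
    selected = {q < fdr_threshold} (strict)."""
    if not 0 < fdr_threshold <= 1:
        raise ValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    scenarios = {s.scenario for s in scores}
    if len(scenarios) > 1:
        raise ValueError(f"scores mix scenarios: {sorted(scenarios)}")
    live = [s for s in scores if not s.disqualified]
    if not live:
        logger.warning("all %d EFMs disqualified; empty selection", len(scores))
        return ScenarioSelection(next(iter(scenarios), ""), set(), fdr_threshold,
                                 mode, list(scores))
    qs = storey_qvalues([s.p_value for s in live])
    for s, q in zip(live, qs):
        s.q_value = float(q)
    selected = {s.efm_id for s in live if s.q_value < fdr_threshold}
    return ScenarioSelection(live[0].scenario, selected, fdr_threshold, mode,
                             list(scores))


def prominent_efms(characteristic: ScenarioSelection,
                   differential: ScenarioSelection) -> set[str]:
    """EFMs selected in both the absolute and the differential arm."""
    if characteristic.scored_ids != differential.scored_ids:
        raise ValueError("selections come from different EFM collections")
    return characteristic.selected & differential.selected


# ---------------------------------------------------------------------------
# Venn reporting


def venn_decompose(named_sets: Mapping[str, Iterable[str]],
                   differential: str | None = None,
                   characteristic: str | None = None,
                   opposing: str | None = None) -> dict:
    """Region counts for 2 or 3 labelled sets (Fig-2-style Venn report).

    Region labels join member set names with ``∩`` and excluded names with
    ``∖`` (e.g. ``AD∩SQ∖CN``); only non-empty regions are reported, and
    the counts partition the union.  When ``differential``,
    ``characteristic`` and ``opposing`` name a differential selection, the
    matching characteristic selection and the opposing scenario's
    characteristic selection, members of the differential set that are
    characteristic *only* in the opposing scenario are additionally
    reported as ``false_positives``.
    """
    sets = {name: set(s) for name, s in named_sets.items()}
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_decompose takes 2 or 3 labelled sets")
    names = list(sets)
    regions: dict[str, int] = {}
    for r in range(len(names), 0, -1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            members = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                members -= sets[n]
            if members:
                label = "∩".join(inside) + "".join(f"∖{n}" for n in outside)
                regions[label] = len(members)
    report: dict = {"regions": regions, "union_size": len(set.union(*sets.values()))}
    if differential and characteristic and opposing:
        fp = sorted((sets[differential] & sets[opposing]) - sets[characteristic])
        report["false_positives"] = fp
    return report


def scores_to_tsv(selection: ScenarioSelection) -> str:
    lines = ["efm\tscenario\tn_support\tn_high\tn_low\tp\tq\tdisqualified\tselected"]
    for s in selection.scores:
        lines.append("\t".join([
            s.efm_id, s.scenario, str(s.n_support), str(s.n_high_in_efm),
            str(s.n_low_in_efm), f"{s.p_value:.6g}", f"{s.q_value:.6g}",
            str(int(s.disqualified)), str(int(s.efm_id in selection.selected)),
        ]))
    return "\n".join(lines) + "\n"
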