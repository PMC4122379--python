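"""Uptake/secretion metabolites of selected EFMs and the prominence table.

Each EFM consumes some external metabolites (inputs, candidate uptake
biomarkers) and produces others (outputs, candidate secretion
biomarkers), given by the sign of its net boundary rate.  The prominence
table counts, per external metabolite and role, how many selected EFMs of
each scenario involve it, and then tiers metabolites for a target
scenario pair (characteristic + differential, e.g. SQ and upSQ):

* **strict** -- present in both target columns and absent from the
  opposing differential column and every other opponent (opposing
  absolute scenario, healthy control);
* **relaxed** -- present in both target columns and absent from the
  opposing differential column, but seen in some other opponent ("if
  possible not in" is a preference, not a hard filter);
* **excluded** -- anything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .efm import EFMCollection, FluxMode
from .network import MetabolicNetwork


@dataclass(frozen=True)
class IOProfile:
    """External metabolites net-consumed (inputs) / net-produced (outputs)
    by one EFM; zero net rates appear in neither set."""

    efm_id: str
    inputs: frozenset[str]
    outputs: frozenset[str]

    def __post_init__(self):
        overlap = self.inputs & self.outputs
        if overlap:
            raise ValueError(f"metabolites both input and output: {sorted(overlap)}")


def io_metabolites(net: MetabolicNetwork, efm: FluxMode) -> IOProfile:
    """Classify each external metabolite by the EFM's net boundary rate
    sum_r coeff(m, r) * v_r: negative = input, positive = output."""
    rxn_by_id = {r.id: r for r in net.reactions}
    inputs, outputs = set(), set()
    for m in net.external_metabolites:
        rate = sum(rxn_by_id[r].stoichiometry.get(m.id, Fraction(0)) * v
                   for r, v in efm.flux.items())
        if rate < 0:
            inputs.add(m.id)
        elif rate > 0:
            outputs.add(m.id)
    return IOProfile(efm.id, frozenset(inputs), frozenset(outputs))


def io_profiles(net: MetabolicNetwork,
                collection: EFMCollection) -> dict[str, IOProfile]:
    return {m.id: io_metabolites(net, m) for m in collection}


@dataclass
class ProminenceTable:
    """Counts of selected EFMs per (metabolite, role U|S) and scenario."""

    counts: pd.DataFrame  # MultiIndex (metabolite, role) × scenario columns

    @property
    def scenarios(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, tiers: Mapping[tuple[str, str], str] | None = None) -> str:
        header = ["metabolite", "role"] + self.scenarios + (["tier"] if tiers else [])
        lines = ["\t".join(header)]
        for (met, role), row in self.counts.iterrows():
            cells = [met, role] + [str(int(v)) for v in row]
            if tiers:
                cells.append(tiers.get((met, role), "excluded"))
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ProminenceTable":
        import io as _io
        df = pd.read_csv(_io.StringIO(text), sep="\t")
        df = df.drop(columns=[c for c in ("tier",) if c in df.columns])
        df = df.set_index(["metabolite", "role"])
        # published-style tables write absent counts as a dash
        df = df.apply(lambda col: col.map(lambda x: 0 if x == "-" else x))
        return cls(df.astype(int))


def build_prominence_table(selections: Mapping[str, set[str]],
                           profiles: Mapping[str, IOProfile],
                           display_names: Mapping[str, str] | None = None,
                           ) -> ProminenceTable:
    """Count selected EFMs carrying each metabolite in each role.

    ``selections`` maps scenario label → selected EFM ids; every selected
    EFM must have a profile.  ``display_names`` optionally maps metabolite
    ids to compartment-stripped display names (biofluid-level identity).
    """
    names = display_names or {}
    cells: dict[tuple[str, str], dict[str, int]] = {}
    scenarios = list(selections)
    for scen, efm_ids in selections.items():
        for eid in efm_ids:
            if eid not in profiles:
                raise KeyError(f"selected EFM {eid!r} has no I/O profile")
            prof = profiles[eid]
            for met in prof.inputs:
                key = (names.get(met, met), "U")
                cells.setdefault(key, {s: 0 for s in scenarios})[scen] += 1
            for met in prof.outputs:
                key = (names.get(met, met), "S")
                cells.setdefault(key, {s: 0 for s in scenarios})[scen] += 1
    if cells:
        index = pd.MultiIndex.from_tuples(sorted(cells),
                                          names=["metabolite", "role"])
        df = pd.DataFrame([[cells[k][s] for s in scenarios] for k in sorted(cells)],
                          index=index, columns=scenarios, dtype=int)
    else:
        index = pd.MultiIndex.from_tuples([], names=["metabolite", "role"])
        df = pd.DataFrame(index=index, columns=scenarios, dtype=int)
    return ProminenceTable(df)


def filter_prominent(table: ProminenceTable, target: tuple[str, str],
                     opposing_differential: str,
                     opponents: tuple[str, ...] = (),
                     ) -> dict[tuple[str, str], str]:
    """Tier each (metabolite, role) row for a target scenario pair.

    ``target`` is (characteristic scenario, differential scenario) — e.g.
    ("SQ", "upSQ"); ``opposing_differential`` the opposite contrast
    ("upAD"); ``opponents`` the soft-excluded scenarios ("AD", "CN").
    strict: > 0 in both targets, 0 in opposing differential and all
    opponents; relaxed: > 0 in both targets, 0 in opposing differential,
    > 0 somewhere among opponents; excluded otherwise.
    """
    for label in (*target, opposing_differential, *opponents):
        if label not in table.scenarios:
            raise KeyError(f"unknown scenario label {label!r}")
    char, diff = target
    tiers: dict[tuple[str, str], str] = {}
    for key, row in table.counts.iterrows():
        in_targets = row[char] > 0 and row[diff] > 0
        if not in_targets or row[opposing_differential] > 0:
            tiers[key] = "excluded"
        elif all(row[o] == 0 for o in opponents):
            tiers[key] = "strict"
        else:
            tiers[key] = "relaxed"
    return tiers
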