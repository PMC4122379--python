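"""Metabolic network data model.

A network is a list of metabolites (each tagged with a compartment and an
``external`` flag marking species that may cross the system boundary) and a
list of reactions with exact rational stoichiometry, a reversibility flag
and an optional GPR rule.  The stoichiometric matrix S has one row per
*internal* metabolite only: external metabolites are unbalanced boundary
species, so uptake/secretion needs no explicit exchange reactions.

Coefficients are stored as :class:`fractions.Fraction` so that downstream
elementarity tests can make exact rank decisions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .gpr import GPRRule, GPRParseError, parse_gpr, serialize_gpr


class NetworkError(ValueError):
    """Raised on an invalid or unparseable network description."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    external: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if not self.compartment:
            raise NetworkError(f"metabolite {self.id!r}: compartment must be non-empty")

    @property
    def display(self) -> str:
        """Bracketed-compartment display form, e.g. ``pyr[c]``."""
        return f"{self.id}[{self.compartment}]"


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool = False
    gpr: GPRRule | None = None

    def __post_init__(self):
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items()}
        if not self.stoichiometry or all(c == 0 for c in self.stoichiometry.values()):
            raise NetworkError(f"reaction {self.id!r}: stoichiometry must have a nonzero coefficient")

    @property
    def equation(self) -> str:
        """Human-readable ``2 A + B -> C`` form (``<->`` if reversible)."""
        def side(items):
            parts = []
            for m, c in items:
                c = abs(c)
                parts.append(m if c == 1 else f"{c} {m}")
            return " + ".join(parts)

        subs = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        prods = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        arrow = "<->" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}"


_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(text: str, reaction_id: str = "?") -> tuple[dict[str, Fraction], bool]:
    """Parse ``2 A + B -> C`` / ``A <-> B`` into (stoichiometry, reversible)."""
    for arrow in _ARROWS:
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            reversible = arrow in ("<->", "<=>")
            break
    else:
        raise NetworkError(f"reaction {reaction_id!r}: no arrow in equation {text!r}")

    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"reaction {reaction_id!r}: empty term in equation")
            m = re.match(r"^((?:\d+(?:[./]\d+)?)\s+)?(\S+)$", term)
            if m is None:
                raise NetworkError(f"reaction {reaction_id!r}: cannot parse term {term!r}")
            coeff = Fraction(m.group(1).strip()) if m.group(1) else Fraction(1)
            met = m.group(2)
            if met in stoich:
                raise NetworkError(f"reaction {reaction_id!r}: metabolite {met!r} appears twice")
            stoich[met] = sign * coeff

    add_side(lhs, -1)
    add_side(rhs, +1)
    return stoich, reversible


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    _met_index: dict[str, Metabolite] = field(init=False, repr=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.reactions:
            raise NetworkError("no reactions")
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate metabolite id(s): {', '.join(dup)}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkError(f"duplicate reaction id(s): {', '.join(dup)}")
        self._met_index = {m.id: m for m in self.metabolites}
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in self._met_index:
                    raise NetworkError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}")

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.external]

    @property
    def external_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.external]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def genes(self) -> frozenset[str]:
        from .gpr import genes_of
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= genes_of(r.gpr)
        return frozenset(out)


def stoichiometric_matrix(net: MetabolicNetwork) -> pd.DataFrame:
    """Internal-metabolite stoichiometric matrix.

    Rows are internal metabolite ids (network order), columns reaction ids;
    entries are exact :class:`~fractions.Fraction` coefficients (negative =
    consumed).  External metabolites contribute no rows.
    """
    rows = [m.id for m in net.internal_metabolites]
    cols = net.reaction_ids
    data = [[r.stoichiometry.get(m, Fraction(0)) for r in net.reactions] for m in rows]
    return pd.DataFrame(data, index=rows, columns=cols, dtype=object)


# ---------------------------------------------------------------------------
# serialization: JSON dialect and a sectioned-TSV alternative


def network_to_json(net: MetabolicNetwork) -> str:
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "external": m.external}
            for m in net.metabolites
        ],
        "reactions": [
            {"id": r.id, "equation": r.equation, "reversible": r.reversible,
             "gpr": serialize_gpr(r.gpr) if r.gpr is not None else ""}
            for r in net.reactions
        ],
    }
    return json.dumps(doc, indent=1)


def network_to_tsv(net: MetabolicNetwork) -> str:
    lines = ["# metabolites", "id\tname\tcompartment\texternal"]
    for m in net.metabolites:
        lines.append(f"{m.id}\t{m.name}\t{m.compartment}\t{int(m.external)}")
    lines += ["# reactions", "id\tequation\treversible\tgpr"]
    for r in net.reactions:
        gpr = serialize_gpr(r.gpr) if r.gpr is not None else ""
        lines.append(f"{r.id}\t{r.equation}\t{int(r.reversible)}\t{gpr}")
    return "\n".join(lines) + "\n"


def _parse_gpr_field(text: str, reaction_id: str) -> GPRRule | None:
    text = (text or "").strip()
    if not text:
        return None
    try:
        return parse_gpr(text)
    except GPRParseError as exc:
        raise NetworkError(f"reaction {reaction_id!r}: malformed GPR: {exc}") from exc


def _truthy(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes")
    return bool(x)


def load_network(text: str) -> MetabolicNetwork:
    """Load a network from its JSON or sectioned-TSV text form.

    The parse is total and order-preserving: every declared metabolite and
    reaction appears in the returned model in file order.  Undeclared
    metabolites, duplicate ids and malformed GPR strings raise
    :class:`NetworkError` naming the offender.
    """
    stripped = text.lstrip()
    if stripped.startswith("{"):
        doc = json.loads(text)
        mets = [Metabolite(id=m["id"], name=m.get("name", ""),
                           compartment=m.get("compartment", "c"),
                           external=_truthy(m.get("external", False)))
                for m in doc.get("metabolites", [])]
        rxns = []
        for r in doc.get("reactions", []):
            stoich, rev = parse_equation(r["equation"], r["id"])
            if "reversible" in r:
                rev = _truthy(r["reversible"])
            rxns.append(Reaction(id=r["id"], stoichiometry=stoich, reversible=rev,
                                 gpr=_parse_gpr_field(r.get("gpr", ""), r["id"])))
        return MetabolicNetwork(mets, rxns)
    return _load_tsv(text)


def _load_tsv(text: str) -> MetabolicNetwork:
    section = None
    header: list[str] = []
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        low = line.strip().lower()
        if low.startswith("#"):
            name = low.lstrip("#").strip()
            if name not in ("metabolites", "reactions"):
                raise NetworkError(f"unknown TSV section {name!r}")
            section, header = name, []
            continue
        if section is None:
            raise NetworkError("TSV network must start with a '# metabolites' or '# reactions' section")
        fields = line.split("\t")
        if not header:
            header = [f.strip().lower() for f in fields]
            continue
        row = dict(zip(header, fields))
        if section == "metabolites":
            mets.append(Metabolite(id=row["id"], name=row.get("name", ""),
                                   compartment=row.get("compartment", "c"),
                                   external=_truthy(row.get("external", "0"))))
        else:
            stoich, rev = parse_equation(row["equation"], row["id"])
            if "reversible" in row:
                rev = _truthy(row["reversible"])
            rxns.append(Reaction(id=row["id"], stoichiometry=stoich, reversible=rev,
                                 gpr=_parse_gpr_field(row.get("gpr", ""), row["id"])))
    return MetabolicNetwork(mets, rxns)
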