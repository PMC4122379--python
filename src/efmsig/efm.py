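"""Elementary flux modes: enumeration, validation and import.

An elementary flux mode (EFM) is a flux vector v with S·v = 0 over the
internal metabolites, v_r >= 0 for every irreversible reaction r, and
support-minimal: no other sign-feasible steady-state vector uses a strict
subset of its reactions.  EFMs are the simplest sustainable pathways of a
network, and every steady-state flux distribution is a non-negative
combination of them.

Enumeration here is the classic nullspace-tableau double-description
scheme (Schuster style) in exact rational arithmetic: reversible reactions
are split into forward/backward columns, internal metabolites are balanced
one at a time by combining rows of opposite sign, non-minimal supports are
pruned after every step, and the two-cycle artifacts of the split are
removed at the end.  Exact Fractions make the support-minimality and rank
decisions free of tolerance choices.  The method is intended for small
networks; genome-scale collections are imported precomputed via
:func:`import_efms`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from .network import MetabolicNetwork, NetworkError, stoichiometric_matrix

logger = logging.getLogger(__name__)

DEFAULT_ENUMERATION_CAP = 30


class EnumerationCapError(RuntimeError):
    """Raised when a network is too large for direct enumeration."""


class ModeError(ValueError):
    """Raised when a flux vector violates a precondition."""


@dataclass(frozen=True)
class FluxMode:
    """A support-minimal steady-state flux vector (nonzero entries only)."""

    id: str
    flux: Mapping[str, Fraction]
    fully_reversible: bool = False  # negation is also a valid orientation

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.flux)

    def __post_init__(self):
        object.__setattr__(self, "flux",
                           {r: Fraction(v) for r, v in self.flux.items() if v != 0})
        if not self.flux:
            raise ModeError(f"mode {self.id!r}: all-zero flux vector is not a mode")


@dataclass
class EFMCollection:
    """An ordered list of flux modes over a common reaction universe."""

    modes: list[FluxMode]
    reaction_ids: list[str]
    provenance: str = "enumerated"  # "enumerated" | "imported"

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, key):
        if isinstance(key, str):
            for m in self.modes:
                if m.id == key:
                    return m
            raise KeyError(key)
        return self.modes[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.modes]

    def supports(self) -> list[frozenset[str]]:
        return [m.support for m in self.modes]


# ---------------------------------------------------------------------------
# exact linear algebra helpers


def _rank(rows: list[list[Fraction]]) -> int:
    """Rank of a rational matrix by Gaussian elimination."""
    mat = [row[:] for row in rows]
    rank = 0
    ncols = len(mat[0]) if mat else 0
    for col in range(ncols):
        pivot = next((i for i in range(rank, len(mat)) if mat[i][col] != 0), None)
        if pivot is None:
            continue
        mat[rank], mat[pivot] = mat[pivot], mat[rank]
        pr = mat[rank]
        for i in range(len(mat)):
            if i != rank and mat[i][col] != 0:
                f = mat[i][col] / pr[col]
                mat[i] = [a - f * b for a, b in zip(mat[i], pr)]
        rank += 1
        if rank == len(mat):
            break
    return rank


def _support(vec: Sequence[Fraction]) -> frozenset[int]:
    return frozenset(i for i, x in enumerate(vec) if x != 0)


# ---------------------------------------------------------------------------
# enumeration


def enumerate_efms(net: MetabolicNetwork,
                   cap: int = DEFAULT_ENUMERATION_CAP) -> EFMCollection:
    """Enumerate all elementary flux modes of a small network.

    Modes are normalized so the first support reaction (network order)
    carries flux of magnitude 1 (sign +1 whenever the orientation allows),
    sorted by (support size, lexicographic support) and labelled EFM1..EFMk.
    A fully reversible mode and its negation count as one mode, reported in
    the orientation that makes its first flux positive and flagged
    ``fully_reversible``.

    Raises :class:`EnumerationCapError` above ``cap`` reactions: direct
    enumeration is for toy networks, genome-scale sets should be imported
    with :func:`import_efms`.
    """
    if len(net.reactions) > cap:
        raise EnumerationCapError(
            f"network has {len(net.reactions)} reactions, above the enumeration "
            f"cap of {cap}; use import_efms() with a precomputed collection instead")

    S = stoichiometric_matrix(net)
    n_int = S.shape[0]
    # split reversible reactions into forward/backward nonnegative columns
    cols: list[tuple[int, int]] = []  # (reaction index, sign)
    for i, r in enumerate(net.reactions):
        cols.append((i, +1))
        if r.reversible:
            cols.append((i, -1))

    # tableau rows: (v over split columns, residual S·v over internal mets)
    rows: list[tuple[list[Fraction], list[Fraction]]] = []
    for j, (i, sign) in enumerate(cols):
        v = [Fraction(0)] * len(cols)
        v[j] = Fraction(1)
        rem = [sign * S.iat[k, i] for k in range(n_int)]
        rows.append((v, rem))

    for k in range(n_int):
        zero = [row for row in rows if row[1][k] == 0]
        pos = [row for row in rows if row[1][k] > 0]
        neg = [row for row in rows if row[1][k] < 0]
        combos: list[tuple[list[Fraction], list[Fraction]]] = []
        for v1, r1 in pos:
            for v2, r2 in neg:
                a, b = -r2[k], r1[k]  # both > 0; a·row1 + b·row2 zeroes met k
                combos.append(([a * x + b * y for x, y in zip(v1, v2)],
                               [a * x + b * y for x, y in zip(r1, r2)]))
        rows = _prune_non_minimal(zero + combos)

    modes = _rows_to_modes(rows, cols, net)
    modes.sort(key=lambda m: (len(m[0]), m[0]))
    flux_modes = [
        FluxMode(id=f"EFM{i + 1}",
                 flux={net.reactions[j].id: x for j, x in zip(supp, fluxes)},
                 fully_reversible=fully_rev)
        for i, (supp, fluxes, fully_rev) in enumerate(modes)
    ]
    return EFMCollection(flux_modes, net.reaction_ids, provenance="enumerated")


def _prune_non_minimal(rows):
    """Drop rows whose support strictly contains another row's.

    Rows with equal support are merged only when proportional (scaling by
    the first nonzero entry; all entries are nonnegative here).
    """
    out = []
    supports: list[frozenset[int]] = []
    seen_scaled: set[tuple] = set()
    for v, rem in rows:
        s = _support(v)
        if any(other < s for other in supports):
            continue
        first = v[min(s)]
        scaled = tuple((i, v[i] / first) for i in sorted(s))
        if scaled in seen_scaled:
            continue
        keep = [i for i, other in enumerate(supports) if not (s < other)]
        if len(keep) != len(out):
            out = [out[i] for i in keep]
            supports = [supports[i] for i in keep]
            seen_scaled = {tuple((j, row[0][j] / row[0][min(sp)])
                                 for j in sorted(sp))
                           for row, sp in zip(out, supports)}
        out.append((v, rem))
        supports.append(s)
        seen_scaled.add(scaled)
    return out


def _rows_to_modes(rows, cols, net):
    """Map split-column tableau rows back to oriented reaction-space modes."""
    seen: set[tuple] = set()
    modes = []
    for v, _rem in rows:
        flux: dict[int, Fraction] = {}
        two_cycle = False
        for x, (i, sign) in zip(v, cols):
            if x == 0:
                continue
            if i in flux:  # both orientations of one reversible reaction
                two_cycle = True
                break
            flux[i] = sign * x
        if two_cycle or not flux:
            continue
        supp = tuple(sorted(flux))
        fully_rev = all(net.reactions[i].reversible for i in supp)
        first = flux[supp[0]]
        if fully_rev and first < 0:
            flux = {i: -x for i, x in flux.items()}
            first = -first
        scale = abs(first)
        fluxes = tuple(flux[i] / scale for i in supp)
        key = (supp, fluxes)
        if key in seen:
            continue
        seen.add(key)
        modes.append((supp, fluxes, fully_rev))
    return modes


# ---------------------------------------------------------------------------
# validation


@dataclass
class ModeDiagnostics:
    """Steady-state / sign diagnostics for a candidate flux vector."""

    max_residual: float
    imbalanced_metabolites: list[str]
    sign_violations: list[str]
    support: frozenset[str]
    ok: bool = field(init=False)
    tolerance: float = 0.0

    def __post_init__(self):
        self.ok = self.max_residual <= self.tolerance and not self.sign_violations


def validate_mode(net: MetabolicNetwork, flux: Mapping[str, object],
                  tolerance: float = 0.0) -> ModeDiagnostics:
    """Report steady-state residuals and irreversibility violations.

    Works on exact or float-valued fluxes; passes iff the largest internal
    imbalance is within ``tolerance`` and no irreversible reaction runs
    backwards.
    """
    rxn_by_id = {r.id: r for r in net.reactions}
    unknown = [r for r in flux if r not in rxn_by_id]
    if unknown:
        raise ModeError(f"unknown reaction id(s): {', '.join(sorted(unknown))}")
    residuals = {}
    for m in net.internal_metabolites:
        total = sum(rxn_by_id[r].stoichiometry.get(m.id, 0) * v
                    for r, v in flux.items())
        residuals[m.id] = total
    max_res = max((abs(x) for x in residuals.values()), default=0)
    violations = [r for r, v in flux.items()
                  if not rxn_by_id[r].reversible and v < 0]
    imbalanced = sorted(m for m, x in residuals.items() if abs(x) > tolerance)
    diag = ModeDiagnostics(max_residual=float(max_res),
                           imbalanced_metabolites=imbalanced,
                           sign_violations=sorted(violations),
                           support=frozenset(r for r, v in flux.items() if v != 0),
                           tolerance=tolerance)
    return diag


def is_elementary(net: MetabolicNetwork, flux: Mapping[str, Fraction]) -> bool:
    """Whether a steady-state, sign-feasible vector is support-minimal.

    Uses the rank criterion: v is elementary iff the internal stoichiometric
    matrix restricted to supp(v) has rank |supp(v)| - 1 (its nullspace on
    the support is the line spanned by v, so no strictly smaller support
    admits a steady-state vector).  The caller must supply a valid mode:
    non-steady-state or sign-violating input raises :class:`ModeError`.
    """
    flux = {r: Fraction(v) for r, v in flux.items() if v != 0}
    if not flux:
        raise ModeError("all-zero vector is not a mode")
    diag = validate_mode(net, flux, tolerance=0.0)
    if diag.max_residual != 0:
        raise ModeError("vector is not at steady state; validate before testing elementarity")
    if diag.sign_violations:
        raise ModeError(f"irreversibility violated by: {', '.join(diag.sign_violations)}")
    supp = sorted(flux)
    rxn_by_id = {r.id: r for r in net.reactions}
    sub = [[rxn_by_id[r].stoichiometry.get(m.id, Fraction(0)) for r in supp]
           for m in net.internal_metabolites]
    if not sub:  # no internal metabolites: only single-reaction modes are minimal
        return len(supp) == 1
    return _rank(sub) == len(supp) - 1


# ---------------------------------------------------------------------------
# import of precomputed collections


def import_efms(text: str, net: MetabolicNetwork | None = None,
                reaction_ids: Sequence[str] | None = None,
                tolerance: float = 1e-6) -> EFMCollection:
    """Import a precomputed EFM collection from TSV text.

    Two layouts are accepted: dense (header ``reaction<TAB>mode1<TAB>...``,
    one row per reaction) and triplet (header ``reaction<TAB>mode<TAB>flux``,
    one nonzero per row).  Mode ids are preserved.  When a network is
    supplied every mode is validated with :func:`validate_mode` at
    ``tolerance``; with only a bare ``reaction_ids`` universe, modes are
    accepted as-is with a logged warning.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty EFM matrix file")
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header] == ["reaction", "mode", "flux"]:
        columns = _parse_triplet(lines[1:])
    else:
        columns = _parse_dense(header, lines[1:])

    if net is not None:
        universe = net.reaction_ids
    elif reaction_ids is not None:
        universe = list(reaction_ids)
    else:
        raise ValueError("either a network or a reaction-id universe is required")
    known = set(universe)

    modes = []
    for mode_id, flux in columns:
        unknown = sorted(set(flux) - known)
        if unknown:
            raise ValueError(f"mode {mode_id!r} references unknown reaction(s): "
                             f"{', '.join(unknown)}")
        nonzero = {r: v for r, v in flux.items() if v != 0}
        if not nonzero:
            raise ValueError(f"mode {mode_id!r}: all-zero column")
        if net is not None:
            diag = validate_mode(net, nonzero, tolerance=tolerance)
            if not diag.ok:
                raise ValueError(
                    f"mode {mode_id!r} fails validation: max residual "
                    f"{diag.max_residual:g}, sign violations {diag.sign_violations}")
        modes.append(FluxMode(id=mode_id, flux=nonzero))
    if net is None:
        logger.warning("imported %d EFMs without a network: steady state not verified",
                       len(modes))
    return EFMCollection(modes, universe, provenance="imported")


def _to_number(s: str) -> Fraction | float:
    try:
        return Fraction(s)
    except ValueError:
        return float(s)


def _parse_dense(header, body):
    mode_ids = [h.strip() for h in header[1:]]
    if not mode_ids:
        raise ValueError("dense EFM matrix has no mode columns")
    flux: list[dict] = [dict() for _ in mode_ids]
    for ln in body:
        fields = ln.split("\t")
        rid = fields[0].strip()
        for j, val in enumerate(fields[1:]):
            x = _to_number(val.strip() or "0")
            if x != 0:
                flux[j][rid] = x
    return list(zip(mode_ids, flux))


def _parse_triplet(body):
    flux: dict[str, dict] = {}
    for ln in body:
        rid, mid, val = (f.strip() for f in ln.split("\t"))
        flux.setdefault(mid, {})[rid] = _to_number(val)
    return list(flux.items())


def efms_to_tsv(collection: EFMCollection) -> str:
    """Dense TSV form of a collection (reactions × modes)."""
    lines = ["\t".join(["reaction"] + collection.ids)]
    for rid in collection.reaction_ids:
        vals = [str(m.flux.get(rid, 0)) for m in collection.modes]
        lines.append("\t".join([rid] + vals))
    return "\n".join(lines) + "\n"
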