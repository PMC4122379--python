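"""End-to-end orchestration and reporting.

``run_pipeline`` wires the stages together for a configured study plan:
load (or enumerate) the EFM collection, discretize expression per
scenario (absolute per group, differential per contrast), project gene
states onto reactions through GPRs, score and select characteristic and
differential EFMs at the configured FDR, intersect them into prominent
EFMs, and emit the state-count summary, Venn decomposition, I/O profiles
and the uptake/secretion prominence table, plus a run manifest.  All
outputs are deterministic text files: the same config and seed reproduce
them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .efm import EFMCollection, efms_to_tsv, enumerate_efms, import_efms
from .expression import (ActivityModel, ExpressionMatrix, GeneStateVector,
                         call_absolute_states, differential_states,
                         expression_from_tsv, states_to_tsv)
from .network import MetabolicNetwork, load_network
from .projection import ReactionStateVector, project_states, reaction_states_to_tsv
from .prominence import build_prominence_table, filter_prominent, io_profiles
from .scoring import (prominent_efms, score_collection, scores_to_tsv,
                      select_efms, venn_decompose)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and scenario plan for one run."""

    network: str = ""
    expression: str = ""
    probe_map: str = ""
    groups: str = ""
    efm_matrix: str | None = None
    absolute_groups: list[str] = field(default_factory=list)
    differential_pairs: list[tuple[str, str]] = field(default_factory=list)
    gene_q_threshold: float = 0.05
    efm_fdr_threshold: float = 0.20
    tau_low: float = 0.1
    probe_fraction: float = 1.0
    sample_fraction: float = 1.0
    mixture_k: float = 3.0
    prior_df: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("gene_q_threshold", "efm_fdr_threshold", "probe_fraction",
                     "sample_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.tau_low <= 1:
            raise ValueError(f"tau_low must be in [0, 1], got {self.tau_low}")
        for a, b in self.differential_pairs:
            for g in (a, b):
                if self.absolute_groups and g not in self.absolute_groups:
                    raise ValueError(
                        f"differential pair ({a}, {b}) references group {g!r} "
                        f"not in absolute_groups")

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        doc = yaml.safe_load(text) or {}
        cfg = cls(**{k: v for k, v in doc.items()})
        cfg.differential_pairs = [tuple(p) for p in cfg.differential_pairs]
        cfg.validate()
        return cfg

    def digest(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def summarize_states(vectors: Mapping[str, GeneStateVector | ReactionStateVector],
                     ) -> pd.DataFrame:
    """Per-scenario counts of +1 / 0 / -1 calls; rows sum to universe size."""
    rows = {}
    for name, vec in vectors.items():
        p, z, m = vec.counts()
        rows[name] = {"plus": p, "zero": z, "minus": m, "total": p + z + m}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["plus", "zero", "minus", "total"])


@dataclass
class PipelineResult:
    config: PipelineConfig
    gene_states: dict[str, GeneStateVector]
    reaction_states: dict[str, ReactionStateVector]
    selections: dict  # scenario → ScenarioSelection
    prominent: dict[str, set[str]]  # group → prominent EFM ids
    venn: dict
    prominence_tables: dict  # group → (ProminenceTable, tiers)
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 net: MetabolicNetwork | None = None,
                 expr: ExpressionMatrix | None = None,
                 efms: EFMCollection | None = None) -> PipelineResult:
    """Execute the full analysis and write all report artifacts.

    Inputs come from the config's paths, or may be passed pre-built (the
    programmatic route used by the simulator and the tests).  Artifacts,
    all TSV/JSON: per-scenario gene and reaction state vectors, the 1/0/-1
    summary table, per-scenario EFM scores, selected / prominent EFM
    lists, Venn region counts with differential false-positive
    diagnostics, I/O profiles and the tiered prominence table, and a run
    manifest (config digest, version, seed).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = net if net is not None else _load_net(config)
    expr = expr if expr is not None else _load_expr(config)
    efms = efms if efms is not None else _load_efms(config, net)

    groups = config.absolute_groups or expr.groups
    model = ActivityModel(k=config.mixture_k).fit(expr.values)

    gene_states: dict[str, GeneStateVector] = {}
    reaction_states: dict[str, ReactionStateVector] = {}
    for grp in groups:
        gene_states[grp] = _call_abs(expr, grp, config, model)
    diff_of_group: dict[str, str] = {}
    for a, b in config.differential_pairs:
        vec, _results = _call_diff(expr, a, b, config)
        gene_states[vec.scenario] = vec
        diff_of_group[a] = vec.scenario
    for name, gsv in gene_states.items():
        reaction_states[name] = project_states(net, gsv)

    selections = {}
    for name, rsv in reaction_states.items():
        mode = "differential" if name in diff_of_group.values() else "characteristic"
        scores = score_collection(efms, rsv, tau_low=config.tau_low)
        selections[name] = select_efms(scores, config.efm_fdr_threshold, mode=mode)

    prominent: dict[str, set[str]] = {}
    for grp, diff_name in diff_of_group.items():
        prominent[grp] = prominent_efms(selections[grp], selections[diff_name])

    venn: dict = {}
    if 2 <= len(groups) <= 3:
        venn["characteristic"] = venn_decompose(
            {g: selections[g].selected for g in groups})
    for a, b in config.differential_pairs:
        da = diff_of_group.get(a)
        if da and b in selections:
            venn[f"{a}_vs_{b}"] = venn_decompose(
                {a: selections[a].selected, da: selections[da].selected,
                 b: selections[b].selected},
                differential=da, characteristic=a, opposing=b)

    profiles = io_profiles(net, efms)
    display = {m.id: (m.name or m.id) for m in net.external_metabolites}
    all_sel = {name: sel.selected for name, sel in selections.items()}
    table = build_prominence_table(all_sel, profiles, display_names=display)
    prominence_tables = {}
    for a, b in config.differential_pairs:
        da, db = diff_of_group.get(a), diff_of_group.get(b)
        if da is None or db is None:
            continue
        opponents = tuple([b] + [g for g in groups if g not in (a, b)])
        tiers = filter_prominent(table, target=(a, da),
                                 opposing_differential=db, opponents=opponents)
        prominence_tables[a] = (table, tiers)

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "efmsig_version": __version__,
        "seed": config.seed,
        "n_reactions": len(net.reactions),
        "n_metabolites": len(net.metabolites),
        "n_efms": len(efms),
        "n_genes": len(expr.genes),
        "n_probes": expr.values.shape[0],
        "n_samples": expr.values.shape[1],
        "activity_threshold": round(model.threshold_, 6),
        "scenarios": sorted(selections),
    }
    result = PipelineResult(config, gene_states, reaction_states, selections,
                            prominent, venn, prominence_tables, manifest)
    _write_artifacts(result, net, efms, profiles, table, outdir)
    return result


_load_net = _stage("load_network")(
    lambda config: load_network(Path(config.network).read_text()))
_load_expr = _stage("load_expression")(
    lambda config: expression_from_tsv(Path(config.expression).read_text(),
                                       Path(config.probe_map).read_text(),
                                       Path(config.groups).read_text()))
_call_abs = _stage("absolute_states")(
    lambda expr, grp, config, model: call_absolute_states(
        expr, grp, probe_fraction=config.probe_fraction,
        sample_fraction=config.sample_fraction, model=model))
_call_diff = _stage("differential_states")(
    lambda expr, a, b, config: differential_states(
        expr, a, b, q_threshold=config.gene_q_threshold,
        prior_df=config.prior_df))


@_stage("load_efms")
def _load_efms(config: PipelineConfig, net: MetabolicNetwork) -> EFMCollection:
    if config.efm_matrix:
        return import_efms(Path(config.efm_matrix).read_text(), net=net)
    return enumerate_efms(net)


def _write_artifacts(result: PipelineResult, net, efms, profiles, table,
                     outdir: Path) -> None:
    for name, gsv in result.gene_states.items():
        (outdir / f"gene_states_{name}.tsv").write_text(states_to_tsv(gsv))
    for name, rsv in result.reaction_states.items():
        (outdir / f"reaction_states_{name}.tsv").write_text(
            reaction_states_to_tsv(rsv))
    summary = pd.concat(
        {"genes": summarize_states(result.gene_states),
         "reactions": summarize_states(result.reaction_states)},
        names=["level", "scenario"])
    (outdir / "state_summary.tsv").write_text(summary.to_csv(sep="\t"))
    for name, sel in result.selections.items():
        (outdir / f"efm_scores_{name}.tsv").write_text(scores_to_tsv(sel))
    (outdir / "efms.tsv").write_text(efms_to_tsv(efms))
    (outdir / "selected_efms.json").write_text(json.dumps(
        {name: sorted(sel.selected) for name, sel in result.selections.items()},
        indent=1))
    (outdir / "prominent_efms.json").write_text(json.dumps(
        {g: sorted(ids) for g, ids in result.prominent.items()}, indent=1))
    (outdir / "venn.json").write_text(json.dumps(result.venn, indent=1,
                                                 ensure_ascii=False))
    (outdir / "io_profiles.json").write_text(json.dumps(
        {eid: {"inputs": sorted(p.inputs), "outputs": sorted(p.outputs)}
         for eid, p in sorted(profiles.items())}, indent=1))
    for grp, (tbl, tiers) in result.prominence_tables.items():
        (outdir / f"prominence_{grp}.tsv").write_text(tbl.to_tsv(tiers))
    if not result.prominence_tables:
        (outdir / "prominence.tsv").write_text(table.to_tsv())
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1,
                                                     sort_keys=True))
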