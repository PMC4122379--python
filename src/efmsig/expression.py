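"""Three-level gene state calls from probe-level expression.

Two complementary discretizations are produced per scenario:

* **absolute** -- within one sample group, each gene is called highly
  (+1), normally (0) or lowly (-1) expressed.  Probe-level active/inactive
  calls come from a present/absent threshold fitted as a two-component
  Gaussian mixture on all log2 intensities (see :class:`ActivityModel`);
  a gene is +1 when (by default) *all* of its probes are active
  in *all* of the group's samples, -1 by the mirror rule, 0 otherwise.
  Both "all" quantifiers can be relaxed to fractions.

* **differential** -- between two groups, each gene is called up (+1),
  unchanged (0) or down (-1) from a moderated two-sample contrast on
  gene-level (probe-averaged) values, with per-gene variances shrunk
  toward the cross-gene mean and p-values converted to Storey q-values;
  the call is sign(effect) when q is below the threshold (default 5%).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Probe × sample log2 intensities with probe→gene and sample→group maps."""

    values: pd.DataFrame  # probes × samples
    probe_to_gene: dict[str, str]
    sample_groups: dict[str, str]

    def __post_init__(self):
        missing = [p for p in self.values.index if p not in self.probe_to_gene]
        if missing:
            raise ValueError(f"probes without a gene mapping: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        unmapped = [s for s in self.values.columns if s not in self.sample_groups]
        if unmapped:
            raise ValueError(f"samples without a group: {unmapped[:5]}")
        if any(not g for g in self.sample_groups.values()):
            raise ValueError("empty group label")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.values.index:
            seen.setdefault(self.probe_to_gene[p], None)
        return list(seen)

    def probes_of(self, gene: str) -> list[str]:
        return [p for p in self.values.index if self.probe_to_gene[p] == gene]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def gene_level(self) -> pd.DataFrame:
        """Gene × sample matrix, probes averaged per gene."""
        gene_index = pd.Series({p: self.probe_to_gene[p] for p in self.values.index})
        out = self.values.groupby(gene_index).mean()
        return out.loc[self.genes]  # preserve first-seen gene order


@dataclass
class GeneStateVector:
    """Per-scenario {-1, 0, +1} gene calls."""

    scenario: str
    states: dict[str, int]

    def __post_init__(self):
        bad = {g: s for g, s in self.states.items() if s not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"states outside {{-1,0,+1}}: {bad}")

    def counts(self) -> tuple[int, int, int]:
        """(n_plus, n_zero, n_minus)."""
        vals = list(self.states.values())
        return vals.count(1), vals.count(0), vals.count(-1)


@dataclass
class DiffGeneResult:
    gene: str
    effect: float  # log2 contrast coefficient, group_a - group_b
    t_stat: float
    p_value: float
    q_value: float = float("nan")


# ---------------------------------------------------------------------------
# absolute arm: present/absent calling


@dataclass
class ActivityModel:
    """Present/absent threshold on log2 intensities.

    Fitted as a two-component Gaussian mixture over *all* intensities of a
    matrix; the threshold is the inactive component's mean plus ``k`` of
    its standard deviations.  A probe-sample is active iff its intensity
    strictly exceeds the threshold.  A fixed threshold may be supplied
    directly, and is also the fallback when the mixture is unidentifiable
    (near-constant data).
    """

    k: float = 3.0
    fixed_threshold: float | None = None
    threshold_: float = field(default=float("nan"), init=False)

    def fit(self, values: np.ndarray | pd.DataFrame) -> "ActivityModel":
        if self.fixed_threshold is not None:
            self.threshold_ = float(self.fixed_threshold)
            return self
        x = np.asarray(values, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 2 or np.std(x) < 1e-12:
            self.threshold_ = float(np.mean(x)) if x.size else 0.0
            logger.warning("activity mixture unidentifiable (constant data); "
                           "falling back to fixed threshold %.3g", self.threshold_)
            return self
        from sklearn.mixture import GaussianMixture
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = GaussianMixture(n_components=2, random_state=0, n_init=2)
            gm.fit(x.reshape(-1, 1))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        lo = int(np.argmin(means))
        self.threshold_ = float(means[lo] + self.k * sds[lo])
        return self


def call_probe_activity(intensities: Sequence[float] | np.ndarray,
                        model: ActivityModel | float) -> np.ndarray:
    """Boolean active calls for one probe's intensities (strict >)."""
    thr = model.threshold_ if isinstance(model, ActivityModel) else float(model)
    return np.asarray(intensities, dtype=float) > thr


def call_absolute_states(expr: ExpressionMatrix, group: str,
                         probe_fraction: float = 1.0,
                         sample_fraction: float = 1.0,
                         model: ActivityModel | None = None) -> GeneStateVector:
    """Absolute three-level calls for one sample group.

    A gene is +1 iff at least ``probe_fraction`` of its probes are active
    in at least ``sample_fraction`` of the group's samples; -1 by the
    mirror rule on inactive calls; 0 otherwise.  The defaults 1.0/1.0 are
    the strict all-probes/all-samples rule; relaxing (e.g. 0.95) trades
    confidence for sensitivity to a single flaky probe.  If relaxation
    makes a gene satisfy both rules, the high call wins, so loosening a
    fraction never shrinks the +1 set.
    """
    if not 0 < probe_fraction <= 1 or not 0 < sample_fraction <= 1:
        raise ValueError("probe_fraction and sample_fraction must be in (0, 1]")
    samples = expr.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    if model is None:
        model = ActivityModel().fit(expr.values)
    elif np.isnan(model.threshold_):
        model.fit(expr.values)
    sub = expr.values[samples]
    active = sub.to_numpy(dtype=float) > model.threshold_
    n_samp = len(samples)

    states: dict[str, int] = {}
    probes_by_gene: dict[str, list[int]] = {}
    for i, p in enumerate(expr.values.index):
        probes_by_gene.setdefault(expr.probe_to_gene[p], []).append(i)
    for gene, idx in probes_by_gene.items():
        act = active[idx]  # probes × samples
        probe_hi = (act.sum(axis=1) >= sample_fraction * n_samp - 1e-9)
        probe_lo = ((~act).sum(axis=1) >= sample_fraction * n_samp - 1e-9)
        n_probes = len(idx)
        hi = probe_hi.sum() >= probe_fraction * n_probes - 1e-9
        lo = probe_lo.sum() >= probe_fraction * n_probes - 1e-9
        states[gene] = 1 if hi else (-1 if lo else 0)
    return GeneStateVector(scenario=group, states=states)


# ---------------------------------------------------------------------------
# differential arm: moderated contrast + Storey q-values


def differential_states(expr: ExpressionMatrix, group_a: str, group_b: str,
                        q_threshold: float = 0.05, prior_df: float = 4.0,
                        ) -> tuple[GeneStateVector, list[DiffGeneResult]]:
    """Up/unchanged/down calls for ``group_a`` relative to ``group_b``.

    Per gene the probe-averaged values are contrasted between the groups;
    the pooled variance is shrunk toward the cross-gene mean variance with
    ``prior_df`` pseudo-degrees of freedom (a transparent stand-in for the
    full empirical-Bayes moderation), t is referred to a t distribution
    with residual + prior df, and q-values control the FDR across genes.
    The state is sign(effect) when q < ``q_threshold`` (strict), else 0;
    swapping the groups negates every nonzero state exactly.
    """
    sa, sb = expr.samples_in(group_a), expr.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples (variance undefined otherwise)")
    gmat = expr.gene_level()
    a = gmat[sa].to_numpy(dtype=float)
    b = gmat[sb].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    effect = a.mean(axis=1) - b.mean(axis=1)
    df = na + nb - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df
    s2_prior = float(np.mean(s2))
    s2_post = (prior_df * s2_prior + df * s2) / (prior_df + df)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0),
                     np.where(effect == 0, 0.0, np.inf * np.sign(effect)))
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    q = storey_qvalues(p)

    genes = list(gmat.index)
    results = [DiffGeneResult(g, float(effect[i]), float(t[i]), float(p[i]),
                              float(q[i]))
               for i, g in enumerate(genes)]
    states = {g: (int(np.sign(effect[i])) if q[i] < q_threshold else 0)
              for i, g in enumerate(genes)}
    scenario = f"up{group_a}"
    return GeneStateVector(scenario=scenario, states=states), results


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def storey_qvalues(p_values: Sequence[float] | np.ndarray,
                   lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                   pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(λ) = #{p > λ} / (m(1-λ)) is computed on the grid and extrapolated
    to λ → max(grid) with a cubic polynomial smoother; if the smoothed
    estimate is non-finite or non-positive the fallback is min(1, mean of
    the grid estimates).  Then q_i = min over p_j >= p_i of
    pi0·m·p_j / rank(p_j).  Fixing ``pi0=1`` reduces exactly to
    Benjamini–Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lam = np.asarray(lambda_grid, dtype=float)
        est = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                coef = np.polyfit(lam, est, deg=3)
                smoothed = float(np.polyval(coef, lam.max()))
            except Exception:
                smoothed = float("nan")
        if not np.isfinite(smoothed) or smoothed <= 0:
            smoothed = float(min(1.0, est.mean()))
            logger.warning("pi0 smoother unstable; falling back to mean estimate %.3g",
                           smoothed)
        # clamp below by 1/m so q-values stay defined when every p is small
        pi0 = min(1.0, max(smoothed, 1.0 / m))
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# TSV I/O


def expression_from_tsv(values_tsv: str, probe_map_tsv: str,
                        groups_tsv: str) -> ExpressionMatrix:
    """Read the expression dialect: values (probe id + sample columns),
    probe→gene and sample→group sidecars, all tab-separated with headers."""
    values = pd.read_csv(io.StringIO(values_tsv), sep="\t", index_col=0)
    pmap = pd.read_csv(io.StringIO(probe_map_tsv), sep="\t")
    gmap = pd.read_csv(io.StringIO(groups_tsv), sep="\t")
    probe_to_gene = dict(zip(pmap.iloc[:, 0].astype(str), pmap.iloc[:, 1].astype(str)))
    sample_groups = dict(zip(gmap.iloc[:, 0].astype(str), gmap.iloc[:, 1].astype(str)))
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, probe_to_gene, sample_groups)


def states_to_tsv(vector: GeneStateVector, kind: str = "gene") -> str:
    lines = [f"{kind}\tstate"]
    lines += [f"{g}\t{s}" for g, s in vector.states.items()]
    return "\n".join(lines) + "\n"
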