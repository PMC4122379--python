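# Methods

## Problem and model

`efmsig` asks which of a metabolic network's elementary flux modes (EFMs) are
supported by gene expression in a given biological scenario, and which boundary
metabolites those modes take up or secrete. An EFM is a flux vector `v` with

* `S·v = 0` over the *internal* metabolites (steady state: production equals
  consumption inside the system boundary),
* `v_r ≥ 0` for every irreversible reaction `r`, and
* minimal support: no other vector satisfying the first two constraints uses a
  strict subset of its reactions.

EFMs are the simplest self-sustaining pathways of the network; every feasible
steady-state flux distribution is a non-negative combination of them. External
metabolites (the boundary species) are modeled as unbalanced — they have no row
in `S` — rather than through explicit exchange reactions. This keeps the toy
glycolysis/TCA network at its three textbook modes (anaerobic glycolysis,
aerobic glycolysis via the TCA cycle, TCA fed by acetate) and makes each mode's
uptake/secretion profile directly readable from its net boundary rates.

## EFM enumeration

Enumeration uses the classic nullspace-tableau double-description scheme in
exact rational arithmetic (`fractions.Fraction`): reversible reactions are
split into forward/backward columns, internal metabolites are balanced one at
a time by combining tableau rows of opposite residual sign, rows whose support
strictly contains another row's support are pruned after every step, and the
two-cycle artifacts of the split (forward+backward of one reaction) are removed
at the end. Exact arithmetic makes both the support-minimality pruning and the
elementarity rank test (`rank(S[:, supp(v)]) = |supp(v)| − 1`) tolerance-free.

Output is deterministic: each mode is scaled so its first support reaction (in
network order) carries flux of magnitude 1, a mode whose support is entirely
reversible is reported in the orientation that makes that flux +1 and flagged
`fully_reversible` (its negation counts as the same mode), and modes are sorted
by (support size, lexicographic support) before receiving ids `EFM1..EFMk`.

Direct enumeration is refused above a configurable cap (default 30 reactions):
the double-description step is exponential in the worst case and genome-scale
collections are expected to be imported precomputed (`import_efms`, dense or
triplet TSV), where each mode is re-validated against the network at a float
tolerance (default 1e-6) since imported fluxes are usually floating point.

## Expression discretization

**Absolute arm.** Probe-level present/absent calls use a single threshold fit
on all log2 intensities of the matrix: a two-component Gaussian mixture, with
threshold = inactive-component mean + `k`·sd (default `k = 3`; strict `>`).
Unlike reference-corpus approaches to present/absent calling, which freeze
per-probe distributions from large archives of arrays, this threshold is
fittable from the one matrix at hand while keeping the same present/absent
semantics. A fixed threshold can be supplied, and is the fallback when
the mixture is unidentifiable (near-constant data). A gene is called highly
expressed (+1) when at least `probe_fraction` of its probes are active in at
least `sample_fraction` of the group's samples (defaults 1.0/1.0, the strict
all-probes/all-samples rule), lowly expressed (−1) by the mirror rule, else 0.
When a relaxed fraction makes a gene satisfy both rules the high call wins, so
loosening a fraction never shrinks the +1 set.

**Differential arm.** Probes are averaged per gene per sample (the simplest
defensible many-probes-to-one-gene summary), and a two-group contrast is
fitted per gene. The pooled variance is shrunk toward the cross-gene mean
variance with `prior_df` pseudo-degrees of freedom (default 4):
`s²_post = (d0·s̄² + df·s²_g)/(d0 + df)`, a transparent fixed-prior rendering
of empirical-Bayes moderation. `t = effect / sqrt(s²_post(1/n_a + 1/n_b))` is
referred to a t distribution with `df + d0` degrees of freedom. The state is
`sign(effect)` when the Storey q-value is strictly below the threshold
(default 5%), else 0. Swapping the group labels negates the effect exactly in
floating point, so the calls are exactly antisymmetric.

**Storey q-values.** `π0(λ) = #{p > λ}/(m(1−λ))` on the grid 0.05..0.95 (step
0.05) is extrapolated to the grid maximum with a cubic polynomial smoother;
if the smoothed value is non-finite or ≤ 0 the fallback is min(1, mean of the
grid estimates), and π0 is clamped below by 1/m so q-values remain defined
when every hypothesis looks alternative. Then
`q_i = min_{p_j ≥ p_i} π0·m·p_j/rank(p_j)`, which with π0 fixed at 1 reduces
exactly to Benjamini–Hochberg.

## GPR projection

Gene states map to reaction states through gene-protein-reaction rules with
AND = min and OR = max over the order −1 < 0 < +1 — the standard extension of
the boolean operators to ordered levels (AND: a complex needs every subunit;
OR: any isozyme suffices). Genes without expression evidence evaluate to 0
(absence of evidence must not force "lowly expressed"), and reactions with no
GPR are 0 and flagged so that scoring can exclude them from the evidence
universe. Note this map is not odd: negating all gene states need not negate
reaction states (OR(+1, −1) = +1 either way), which is why an exact gene-level
mirror between a contrast and its label swap generally breaks at reaction
level.

## EFM scoring and selection

For one scenario, let N be the GPR-covered reactions that appear in at least
one EFM of the collection, and K those at +1. An EFM with GPR-covered support
of size n, x of them at +1, gets the one-sided hypergeometric upper-tail
p-value `P[X ≥ x]`, `X ~ Hypergeom(N, K, n)`. An EFM whose covered support has
a −1 fraction above `tau_low` (default 0.1; set 0 for the strict reading of
"few lowly expressed reactions") is disqualified regardless of p, as is an EFM
with no covered support. q-values over the non-disqualified scores use the
same Storey machinery as genes, and the selection is `{q < fdr}` (default
FDR 20%, strict). Flux magnitudes are deliberately ignored — the score is
support-only — which is flagged as future work.

"Characteristic" selections come from absolute states, "differential" ones
from contrast states, and "prominent" EFMs are the exact intersection of the
two for a scenario. Venn decomposition reports every non-empty region of 2–3
labelled selections (counts partition the union) and flags, for a
differential-vs-characteristic comparison, differential EFMs characteristic
only in the opposing scenario as false positives.

## Uptake/secretion prominence

An EFM's net boundary rate for external metabolite m is
`Σ_r coeff(m, r)·v_r`: negative → input (uptake, U), positive → output
(secretion, S), zero → absent. The prominence table counts selected EFMs per
(metabolite, role, scenario); metabolite identity is compartment-stripped via
the display name (biofluid-level identity). Tiering for a target pair
(characteristic scenario, its differential twin): **strict** needs presence in
both target columns and absence from the opposing differential column and all
other opponents (opposing absolute scenario, control); **relaxed** tolerates
presence in the soft opponents but never in the opposing differential column
("if possible not in" is a preference — a hard filter would exclude rows that
plainly belong in the table); everything else is **excluded**. Dashes in
reported tables are read as zero counts.

## Synthetic data

The generator emulates a probe-level microarray study over 2–3 groups:
bimodal log2 intensities (inactive N(5, 1), active N(11, 1) — the minimal
model under which present/absent calling is well-posed), 1–3 probes per gene,
i.i.d. per-probe-per-sample measurement noise (sd 0.5), and a planted effect
of 2 log2 units added to the active mean for the genes of "planted" EFMs'
support reactions in designated groups; all other GPR genes and decoy genes
draw from the inactive component. Defaults are three groups of 10 samples.
Ground truth (per-group gene states, planted EFM ids, per-probe component
membership) is returned alongside, so recovery can be measured rather than
eyeballed. The toy fixtures are the glycolysis/TCA network (coefficients
1 Glc → 2 Pyr and Cit → OAA + 2 CO2, a lumping that does not change the mode
count or supports; one gene per reaction, multi-gene GPRs exercised through
the random-network generator) and a parallel-pathways testbed whose EFM ↔
boundary-metabolite map is known by construction.

What the generator does *not* emulate: array normalization artifacts,
probe-sequence effects, correlated noise, batch structure across data sources,
partially overlapping pathway regulation, or post-transcriptional control.
Passing recovery tests therefore shows the inference machinery is correct
under its own model, not that real tumor data will separate this cleanly.

## Numerical and design choices

* Network coefficients, enumeration and elementarity: exact rationals; no
  tolerances anywhere in enumeration. Imported float collections validated at
  1e-6 residual by default.
* Threshold comparisons are strict everywhere (activity `>`, gene q `<` 5%,
  EFM q `<` 20%), so boundary ties fall on the conservative side.
* Problem sizes in the test-bench studies — toy networks of ≤ 8 reactions for
  oracle equivalence, 100-pathway collections with 10 planted EFMs and
  10 samples per group over 20 seeds for recovery — were chosen as the
  smallest instances at which every mechanism (mixture calling, moderation,
  FDR, disqualification, tiering) is genuinely exercised.
* Pipeline outputs are plain TSV/JSON with fixed ordering and formatting; the
  same config and seed reproduce every artifact byte for byte.

## Limitations

* Direct enumeration is for small networks only; genome-scale analyses must
  import a precomputed EFM collection.
* The mixture threshold shares information across all probes of a matrix,
  unlike per-probe reference-corpus calibration; on arrays with strong
  probe-affinity spread it will miscall probes whose dynamic range sits
  inside one component.
* The moderated contrast uses a fixed prior df rather than estimating it;
  with very few genes the cross-gene variance prior is itself noisy.
* Enrichment ignores flux magnitudes and treats reactions as exchangeable
  within the covered universe; dependence between overlapping EFMs is handled
  only through the FDR machinery, not modeled.
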