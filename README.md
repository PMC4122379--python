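# efmsig

Elementary-flux-mode signatures from gene expression: find the metabolic
pathways a transcriptome actually supports, and the uptake/secretion
metabolites that tell two biological scenarios apart.

## The problem

Cellular metabolism can be decomposed into **elementary flux modes** (EFMs):
flux vectors `v` satisfying steady state on internal metabolites, `S·v = 0`,
respecting irreversibility, `v_r ≥ 0` for irreversible `r`, and with minimal
support — removing any participating enzyme disrupts the pathway. EFMs are the
simplest self-sustaining routes through a metabolic network; every feasible
steady-state flux pattern is a non-negative combination of them.

Which modes dominate differs between conditions — the Warburg effect, for
instance, is the prevalence of the anaerobic-glycolysis mode in tumors.
`efmsig` integrates probe-level gene expression with an EFM collection to rank
modes per scenario, for researchers comparing disease subtypes or tissues with
a constraint-based metabolic model in hand:

1. **Discretize** expression to three-level gene states (−1/0/+1): *absolute*
   (lowly/normally/highly expressed within a group, via a present/absent
   mixture threshold and an all-probes/all-samples rule) and *differential*
   (down/unchanged/up between two groups, via a moderated contrast with
   Storey q-values, default q < 5%).
2. **Project** gene states onto reactions through gene-protein-reaction (GPR)
   rules with AND = min, OR = max.
3. **Score** each EFM by one-sided hypergeometric enrichment of +1 reactions
   in its GPR-covered support, disqualifying modes with more than a small
   fraction (default 10%) of −1 reactions, and select at FDR < 20%:
   **characteristic** EFMs (absolute arm), **differential** EFMs (contrast
   arm), and **prominent** EFMs (both at once).
4. **Translate** selected modes into candidate biomarkers: each EFM's net
   boundary rates give its uptake (U) and secretion (S) metabolites, tabulated
   per scenario and tiered (strict/relaxed/excluded) by specificity to a
   target scenario pair.

EFM enumeration (exact-rational nullspace tableau) is built in for small
networks; genome-scale collections are imported precomputed. A synthetic-data
module generates complete studies with planted signal and ground truth.

## Worked example

Generate a toy study — the glycolysis/TCA network with one EFM planted per
cancer group (anaerobic glycolysis in AD, acetate-fed TCA in SQ; control CN
has nothing planted) — and run the whole pipeline:

```bash
efmsig simulate --seed 5 --out study/
cat > cfg.yaml <<'YAML'
network: study/network.json
expression: study/expression.tsv
probe_map: study/probe_map.tsv
groups: study/sample_groups.tsv
efm_matrix: study/efms.tsv
absolute_groups: [AD, SQ, CN]
differential_pairs: [[AD, SQ], [SQ, AD]]
YAML
efmsig run --config cfg.yaml --out out/
```

The network has 8 metabolites (4 boundary), 6 reactions and exactly 3 EFMs:

| id | pathway | flux | inputs → outputs |
|----|---------|------|------------------|
| EFM1 | anaerobic glycolysis | R_glyc:1, R_ldh:2 | D-Glc → D-Lac |
| EFM2 | TCA fed by acetate | R_ack:1, R_cs:1, R_tca:1 | Ac → CO2 |
| EFM3 | aerobic glycolysis via TCA | R_glyc:1, R_pdh:2, R_cs:2, R_tca:2 | D-Glc → CO2 |

`out/state_summary.tsv` shows the per-scenario +1/0/−1 counts over the 16
genes (6 GPR genes + 10 decoys) and 6 reactions; note the exact gene-level
mirror between the label-swapped contrasts (upAD 2/11/3 vs upSQ 3/11/2):

```
level	scenario	plus	zero	minus	total
genes	upAD	2	11	3	16
genes	upSQ	3	11	2	16
reactions	SQ	3	0	3	6
...
```

`out/efm_scores_SQ.tsv` shows why EFM2 is characteristic for SQ: its three
support reactions are all highly expressed (3 of 3 drawn from the 3 high
reactions among 6, p = 1/20 = 0.05, q = 0.05 < 0.20), while EFM1 and EFM3
carry lowly-expressed reactions and are disqualified:

```
efm	scenario	n_support	n_high	n_low	p	q	disqualified	selected
EFM1	SQ	2	0	2	1	nan	1	0
EFM2	SQ	3	3	0	0.05	0.05	0	1
EFM3	SQ	4	2	2	0.8	nan	1	0
```

The same mode is selected in the upSQ contrast, so `out/prominent_efms.json`
recovers exactly what was planted:

```json
{"AD": ["EFM1"], "SQ": ["EFM2"]}
```

and the prominence table (`out/prominence_SQ.tsv`) tiers acetate (U) and — for
AD — lactate (S) as strict scenario-specific boundary metabolites. Everything
is reproducible byte for byte given the config and seed.

The same analysis is available as a library (`efmsig.run_pipeline`, or the
individual stages `enumerate_efms`, `call_absolute_states`,
`differential_states`, `project_states`, `score_collection`, `select_efms`,
`prominent_efms`, `io_metabolites`, `build_prominence_table`).

## Layout

```
src/efmsig/
  network.py     metabolic network model, JSON/TSV dialects, S matrix
  gpr.py         GPR grammar, parser, three-valued evaluation
  efm.py         EFM enumeration, validation, import of precomputed sets
  expression.py  absolute + differential discretization, Storey q-values
  projection.py  gene→reaction state projection
  scoring.py     enrichment, FDR selection, prominent EFMs, Venn reports
  prominence.py  uptake/secretion profiles and the prominence table
  simulate.py    toy fixtures, random networks, planted expression data
  pipeline.py    end-to-end orchestration, summaries, manifest
  cli.py         `efmsig` command-line entry points
```

See `docs/methods.md` for the statistical model, parameter defaults and known
limitations.
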