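# psynet

Psychosocial symptom-network analysis for questionnaire studies: scale
scoring, regularized partial-correlation network estimation, centrality
and stability quantification, permutation-based group comparison, and a
node–outcome linkage analysis — built around a study design linking
psychosocial problems (depression, anxiety, loneliness, self-esteem,
perceived social support, sociosexual orientation, internalized
homonegativity) to high-risk sexual behavior among men who have sex with
men.

## Who this is for

Researchers running (or auditing) psychometric network analyses on
item-level questionnaire data, who want the full pipeline — from raw CSV
responses to comparable, stability-checked networks — as tested,
scriptable Python instead of a collection of R snippets. Because raw data
of the motivating study are not public, the package ships a synthetic
cohort generator that reproduces the study's marginal distributions and
published network backbone, so every stage can be exercised and validated
end to end.

## The model

Each of 37 nodes (29 individual items of PHQ-9 / GAD-7 / UCLA-3 / RSES
plus 8 subscale scores of MSPSS, SOI-R attitude/desire and SIHS) is a
variable in a Gaussian graphical model: edges are partial correlations,
i.e. associations remaining after conditioning on all other nodes.
Estimation is the graphical lasso on pairwise Spearman correlations, the
l1-penalized likelihood

&nbsp;&nbsp;max_K  log det K − tr(R K) − λ ‖K‖₁,off

with λ selected by the extended BIC (EBIC, γ = 0.5). Per node the
package computes strength Σ|w|, expected influence Σw, betweenness and
closeness (shortest paths on distances 1/|w|); stability via case-dropping
bootstrap (CS coefficient); group differences via permutation tests on
the maximum edge difference and global strength; and "connection values"
— Spearman correlations of each node with a composite risk score
(condom-use code + partner-count code) — regressed on centrality across
nodes. See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from psynet import (simulate_study, ScaleScorer, GaussianGraphicalModel,
                    centrality_profile, composite_risk, connection_values,
                    centrality_vs_connection)

sim = simulate_study(n=405, seed=1)                 # synthetic cohort
nodes = ScaleScorer().fit(sim.cohort).transform(sim.cohort)   # 405 x 37
model = GaussianGraphicalModel().fit(nodes)         # EBIC graphical lasso
print("selected penalty:", round(model.alpha_, 3), "| edges:", model.n_edges_)
print(model.edge_list().nlargest(5, "weight"))

prof = centrality_profile(model.weights_)
risk = composite_risk(sim.cohort)["risk_score"]
cv = connection_values(nodes, risk)
reg = centrality_vs_connection(prof, cv)
print("slope:", round(reg.slope_, 3), "p:", f"{reg.pvalue_:.1e}")
```

Output (seed 1):

```
selected penalty: 0.108 | edges: 148
   node_i    node_j   weight
  SOI_ATT   SOI_DES 0.423059
    UCLA1     UCLA2 0.380383
    UCLA2     UCLA3 0.344311
MSPSS_FAM MSPSS_FRI 0.343245
MSPSS_FAM  MSPSS_SO 0.276848
slope: -0.739 p: 3.0e-05
```

The strongest edges sit inside constructs (the two sociosexual facets,
the loneliness items, the support subscales), as expected for
questionnaire data. The connection value of sociosexual desire is
positive (+0.36: more desire for uncommitted sex, more risk behavior)
while *feeling tired* is negative (−0.52: worse emotional symptoms
associate with *less* risk behavior here), and the negative regression
slope says that, across nodes, higher expected-influence centrality goes
with lower (more negative) connection values.

A `psynet` command-line interface wraps the same stages
(`psynet all --out results/run1 --seed 1`, or `simulate` / `score` /
`estimate` / `centrality` / `stability` / `compare` / `link` individually,
configured by a YAML file via `--config`). All outputs are plain
CSV/TSV/JSON plus a manifest recording seed and parameters; identical
config and seed reproduce identical files.

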