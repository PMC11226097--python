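# gsmm-lpca

Compare collections of genome-scale metabolic models (GSMMs) through the
reactions they contain — and explain *why* they cluster, pathway by pathway.

A collection of GSMMs (strains of a genus, tissue-specific reconstructions,
a phylum-wide resource) can be summarised as a binary **pan-reaction
matrix** `X ∈ {0,1}^{N×R}`: one row per model, one column per reaction
observed in at least one model. Columns that are constant across the
collection carry no comparative signal; removing them yields the
**differential matrix** `ΔX`. Classical PCA is a poor fit for such 0/1
data, so this package implements **logistic PCA (LPCA)**: each entry is
encoded as a saturated Bernoulli natural parameter `Θ = m(2ΔX − 1)` and
projected onto a rank-k subspace,

```
Θ̂ = 1μᵀ + (Θ − 1μᵀ)UUᵀ,        S = (Θ − 1μᵀ)U,
```

with the mean vector `μ` and orthonormal loadings `U` chosen to minimise
the Bernoulli deviance

```
D(ΔX | Θ̂) = −2 Σₙᵣ [ ΔXₙᵣ Θ̂ₙᵣ − log(1 + exp Θ̂ₙᵣ) ].
```

The optimiser is a from-scratch majorization-minimization scheme with a
guaranteed monotone deviance descent. Unlike t-SNE or Jaccard heatmaps,
the scores `S` come with reaction-level loadings: averaging the loading
vectors within each metabolic subsystem (glycolysis, murein biosynthesis,
…) and ranking subsystems by `|avg(Uʲ)|` (norm of the average) or
`avg|Uʲ|` (average of norms) names the pathways that drive the observed
separation. Companion analyses validate and cross-check the picture:
Jaccard similarity between reaction sets, hierarchical clustering of score
distances with cophenetic correlation against an external phylogeny, and a
multinomial-logistic-regression (MLR) importance ranking for pre-defined
clades or tissue classes.

Intended users: modellers and comparative genomicists who curate or
consume GSMM collections (SBML Level 3 with fbc/groups, or COBRA JSON) and
want a mechanistically interpretable alternative to black-box embeddings.

## Worked example

Everything below runs on a synthetic collection with known ground truth
(three planted clusters of 40 models; each cluster has a 30-reaction
discriminative subsystem present at probability 0.9 inside the cluster and
0.1 outside; 210 background reactions at probability 0.5):

```python
from gsmm_lpca import differentialize, fit_lpca, subsystem_ranking
from gsmm_lpca.synthgen import SynthSpec, generate_matrix

spec = SynthSpec(seed=7)          # 120 models, 300 reactions, 3 clusters
raw, subsystems, truth = generate_matrix(spec)
matrix, report = differentialize(raw)
print(f"differential matrix: {matrix.shape[0]} x {matrix.shape[1]} "
      f"(dropped {report.dropped_all_ones + report.dropped_all_zeros} constant columns)")

model = fit_lpca(matrix, k=2, m=4.0)
print(f"deviance {model.deviance:.1f} after {model.n_iter} iterations")

ranking = subsystem_ranking(model, subsystems)
print(ranking[["norm_of_avg", "avg_of_norms", "R_j"]].head(5).round(4))
```

prints

```
differential matrix: 120 x 300 (dropped 0 constant columns)
deviance 40799.4 after 92 iterations
                norm_of_avg  avg_of_norms  R_j
subsystem
disc_cluster_2       0.1348        0.1374   30
disc_cluster_1       0.1279        0.1296   30
disc_cluster_3       0.1262        0.1275   30
background_06        0.0064        0.0160   30
background_01        0.0043        0.0117   30
```

The three planted discriminative subsystems top the ranking by an order of
magnitude: `norm_of_avg` is the length of the subsystem's average loading
vector over the first two components (coherent direction), `avg_of_norms`
the average reaction loading length (magnitude regardless of direction),
and `R_j` the subsystem's reaction count. The fitted scores `model.S`
separate the three clusters completely (k-means on the first two
components recovers the planted labels with adjusted Rand index 1.0).

The same analysis is scriptable from the shell:

```sh
gsmm-lpca simulate --seed 7 --out sim/
gsmm-lpca lpca --matrix sim/matrix.tsv --k 2 --m 4 --out fit
gsmm-lpca mlr --matrix sim/matrix.tsv --labels sim/labels.tsv \
              --subsystems sim/subsystems.tsv --out fit
gsmm-lpca run --config run.yaml     # full pipeline with JSON sidecars
```

and `gsmm-lpca build-matrix --models DIR --format sbml --out pan` starts
from a directory of real model files instead of simulations.

## Layout

- `gsmm_lpca.reaction_matrix` — pan/differential matrices, subsystem maps,
  SBML/JSON readers, expression-based presence calls (nTPM > threshold
  through gene-reaction rules)
- `gsmm_lpca.lpca` — the logistic PCA core (deviance, MM fit, scores,
  probabilities, scale selection)
- `gsmm_lpca.loadings` — reaction/subsystem loading vectors and rankings
- `gsmm_lpca.similarity` — Jaccard, score distances, dendrograms,
  cophenetic correlation, Newick I/O
- `gsmm_lpca.mlr` — multinomial-logistic subsystem importance
- `gsmm_lpca.synthgen` — planted-cluster fixture generator (matrices,
  trees, model files, expression tables)
- `gsmm_lpca.pipeline` / `gsmm_lpca.cli` — end-to-end runner and the
  `gsmm-lpca` command

See `docs/methods.md` for the model, algorithmic choices, and limitations.
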