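# Methods

## Model

A collection of N genome-scale metabolic models over R reactions is a
binary matrix `X`; entry (n, r) indicates that reaction r occurs in model
n. Constant columns are removed before analysis (the *differential*
matrix ΔX), since a reaction present in every model, or in none, cannot
discriminate between models and — being infinitely confident under a
Bernoulli likelihood — would push its mean parameter to infinity during
fitting.

Logistic PCA treats each entry as a Bernoulli observation and works on the
natural-parameter (log-odds) scale. The observed data are encoded as
saturated natural parameters

    Θ = m (2 ΔX − 1),   Θ ∈ {−m, +m}^{N×R},

where the scale m > 0 sets how extreme the saturated log-odds are (m = 4
corresponds to saturated probabilities σ(±4) ≈ 0.018/0.982). The rank-k
reconstruction is the projection

    Θ̂ = 1 μᵀ + (Θ − 1 μᵀ) U Uᵀ,

with μ ∈ R^R a mean (main-effect) vector and U ∈ R^{R×k} orthonormal
loadings, chosen to minimise the Bernoulli deviance

    D(ΔX | Θ̂) = −2 Σ_{n,r} [ ΔX_{n,r} Θ̂_{n,r} − log(1 + e^{Θ̂_{n,r}}) ].

Scores are S = (Θ − 1 μᵀ) U; because the projection only involves μ and U,
*new* models (rows not used in fitting) can be projected onto fitted
components, and fitted probabilities are σ(Θ̂).

## Optimisation

The deviance is minimised by majorization-minimization (MM) built on the
uniform quadratic bound for the logistic log-partition (curvature 1/4).
Per iteration, with current reconstruction Θ̂:

1. working matrix `Z = Θ̂ + 4 (ΔX − σ(Θ̂))`;
2. mean update (U fixed): `μ = (I − UUᵀ) · colmean(Z − Θ U Uᵀ)` — the
   exact minimiser of the majorizer, with μ kept orthogonal to range(U)
   (the component inside range(U) is absorbed by the projection and is
   not identified);
3. loading update (μ fixed): U ← top-k eigenvectors of the symmetric
   matrix `Θ̃ᵀẐ + ẐᵀΘ̃ − Θ̃ᵀΘ̃`, where Θ̃ = Θ − 1μᵀ and Ẑ = Z − 1μᵀ.

Both block updates minimise the majorized least-squares objective in
closed form, so every iteration decreases the deviance; the test suite
asserts monotonicity (tolerance 1e−9) and column orthonormality (1e−8) on
every fit. Convergence is declared when the relative deviance change
drops below `tol` (default 1e−6) or after `max_iter` (default 1000)
iterations.

Numerical choices:

- the deviance uses the softplus identity
  `log(1+e^t) = max(t,0) + log1p(e^{−|t|})`, accurate for |t| up to
  several hundred;
- initialisation is deterministic: μ⁰ = column means of Θ, U⁰ = top-k
  right singular vectors of Θ − 1μ⁰ᵀ;
- a fixed sign convention (the largest-magnitude loading of each
  component is non-negative) makes repeated fits bit-identical;
- `partial_eigen=True` switches the eigen step to an iterative top-k
  solver with a deterministic start vector, useful when R is large; it
  agrees with the dense path to 1e−6 in deviance on test instances;
- constant columns, if present, are retained with a warning and their μ
  entries clamped to ±10m to avoid divergence;
- the deviance surface is non-convex and on very small matrices (a
  handful of rows/columns) the MM iteration can settle in a secondary
  basin. `LPCAConfig.n_restarts` reruns the same monotone iteration from
  seeded random starts (μ ~ N(0, m²), U from a QR of Gaussians) and keeps
  the lowest-deviance solution; the deterministic start wins ties. The
  default is 0 restarts — at the scales the method targets (dozens of
  models, hundreds of reactions) the deterministic fit has been the best
  found in all our checks — while the tiny-instance optimiser tests run
  with 30 restarts, where the result matches a 10,000-restart brute-force
  search to better than 1e−4 deviance units.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 2 | number of components; the subsystem analysis reads the first two |
| `m` | 4.0 | saturated log-odds scale; `"auto"` selects from a grid {2,…,12} by refitting and keeping the deviance minimiser (ties → smallest m). The automatic rule is a deviance-grid stand-in and is flagged as `auto-grid` in the model metadata |
| `tol` | 1e−6 | relative deviance-change convergence threshold |
| `max_iter` | 1000 | iteration cap |
| `n_restarts` | 0 | seeded random MM restarts (see above) |

Larger m lets the reconstruction chase the data harder (with k close to
min(N,R) the mean reconstruction error decreases monotonically in m);
smaller m regularises. Cross-validated choice of k is out of scope; k = 2
matches the visualisation-driven use of the method.

## Subsystem statistics

Each reaction r has a loading vector U_{r,·} over the first `n_comp`
components (default 2). For subsystem j with reaction set R_j:

- average loading vector: `avg(Uʲ)_i = (1/|R_j|) Σ_{r∈R_j} U_{r,i}`;
- **norm of average** `|avg(Uʲ)|` — rewards subsystems whose reactions
  load coherently in one direction; reactions pointing in opposite
  directions cancel;
- **average of norms** `avg|Uʲ| = (1/|R_j|) Σ_r |U_{r,·}|` — direction
  blind.

By the triangle inequality `|avg(Uʲ)| ≤ avg|Uʲ|`, with equality for
single-reaction subsystems; both inequalities are asserted on every
ranking the package produces. Both statistics are reported raw and
max-normalised (divided by the per-statistic maximum over subsystems, so
the top subsystem scores exactly 1; normalisation is per method, never
joint). Ties in any ranking break lexicographically by subsystem name,
so outputs are deterministic. Reactions without a subsystem annotation
are pooled under "Unassigned"; the pool is kept in all tables but
excluded from the default top-drivers report (a flag re-includes it),
since an average over unannotated reactions has no pathway reading.

## Similarity and tree validation

Jaccard coefficients J(A,B) = |A∩B| / |A∪B| compare the differential
reaction sets of two models directly; two empty supports are defined as
J = 1 (identical emptiness) and logged — real collections never hit this.
Score-space structure is assessed by Euclidean or Manhattan distances
between score rows, agglomerated with complete linkage by default
(average/single available). A dendrogram is compared with an external
phylogeny via the cophenetic correlation coefficient: Pearson correlation
(Spearman optional) of the pairwise cophenetic distances — merge heights
for dendrograms, patristic branch-length distances for Newick trees —
aligned by leaf id over the strict upper triangle. Manhattan distances
are the recommended metric for binary-derived scores; on hierarchical
synthetic fixtures both metrics recover the generating tree with
correlation > 0.9.

## MLR importance

For pre-defined classes (clades, tissue types, planted clusters), each
reaction is related to class membership by a multinomial logistic model
with an intercept and the reaction's 0/1 presence as the only predictor,
fitted per reaction by penalised maximum likelihood. With a single binary
predictor the likelihood depends on the data only through the 2×C count
table, so each fit is a small convex problem solved by damped Newton
iterations on the count sufficient statistics; the fits match a generic
BFGS optimisation of the per-sample likelihood to 1e−6.

Design choices worth spelling out:

- **Per-reaction fits, not one joint model.** With R ≫ N a joint
  R-predictor multinomial fit is non-identifiable; per-reaction fits are
  the default and a joint ridge fit (`fit_mlr(..., joint=True)`, backed by
  scikit-learn) is available for sensitivity analysis. Numbers from the
  two modes are not interchangeable.
- **Reference class and reported coefficients.** The lexicographically
  first class is the reference; reported coefficient tables contain the
  C−1 non-reference columns (reference coefficients are identically 0).
- **Class-centered ridge and importance.** The ridge penalty (default
  λ = 1e−4; separation is guaranteed to occur with binary predictors and
  several classes, and an unpenalised fit that fails to converge is
  automatically refitted at 1e−4 with a notice) acts on the
  *class-centered* slope vector, and a reaction's importance is the
  Euclidean norm of that centered vector. Centering matters: under a
  reference-pinned parameterisation, switching the reference class shifts
  every slope by a constant, so the raw slope norm would depend on which
  class happens to sort first. The centered statistic — and with the
  centered penalty, the fitted distribution itself — is exactly invariant
  under renaming classes, which the test suite asserts.

Subsystem importance averages the per-reaction norms within each
subsystem (max-normalised as above). `compare_rankings` reports the top-n
overlap with the LPCA ranking, the Spearman correlation over shared
subsystems, and the per-method count of subsystems above 0.5 after
normalisation.

## Synthetic data: what it emulates, and what it does not

`synthgen` produces the fixtures every stage is tested on. The canonical
conditions are N = 120 models in K = 3 equal clusters, R = 300 reactions:
one 30-reaction discriminative subsystem per cluster with presence
probability 0.9 inside its cluster and 0.1 outside, and 210 background
reactions at probability 0.5 split into 30-reaction subsystems. These
defaults make the planted separation strong and the expected ranking
unambiguous; they are the package's reference acceptance conditions, not
a sensitivity frontier. In hierarchical mode clusters are paired into
superclusters with additional supercluster-level discriminative blocks,
and the generator emits the true ultrametric tree (cluster join depth 1,
supercluster depth 2, root depth 3) for cophenetic validation. The
generator can also materialise the matrix as per-model SBML/JSON files
(round-trip exact) and construct expression tables + gene rules that
reproduce a target presence pattern through the nTPM-threshold rule.

What it deliberately does not emulate: real metabolic network topology or
stoichiometry, correlated reaction presence within pathways beyond the
block structure, annotation noise (conflicting or missing subsystem
labels at realistic rates), unbalanced cluster sizes by default, or the
>50 % unassigned-reaction regimes seen in some curated resources. Passing
tests therefore demonstrate correctness of the computations and recovery
under clean planted signal — not robustness to the full messiness of
curated GSMM collections.

Problem sizes used by the test suite and the acceptance script — 120×300
canonical fits (20 replicates), 10 hierarchical replicates for tree
validation, and 5×4/6×5 instances for the brute-force optimiser
comparison — are the package's reference conditions chosen so the whole
suite runs in minutes on one CPU.

## Other conventions and degenerate inputs

- Pan-matrix columns are ordered lexicographically by reaction id; row
  order follows the input model order. Subsystem annotation conflicts
  between models are resolved by majority vote, ties lexicographic, all
  conflicts logged; an explicit remapping table overrides any merged
  assignment (supporting manual re-annotations such as moving a
  misassigned reaction to a newly created subsystem).
- Expression-based presence calls are strict: a gene counts as expressed
  only if nTPM > threshold (default 0.2), a gene exactly at the threshold
  is silent. Reactions without a gene rule are never called present, so
  gap-filled content without genetic evidence is excluded. Gene rules use
  COBRA grammar (identifiers, and/or, parentheses; no negation), hence
  presence calls are monotone in the threshold.
- A differential matrix with zero columns is legal and flagged; an
  all-constant matrix is a fit error; k ≥ min(N, R) is an error.
- Cophenetic correlation requires identical leaf sets and ≥ 3 leaves;
  zero-variance cophenetic distances are reported as an error rather than
  NaN.

## Known limitations

- The deviance objective is non-convex; MM guarantees monotone descent to
  a stationary point, not a global optimum (see restarts above).
- The automatic m selection refits at every grid value — O(|grid|) full
  fits — and is a pragmatic stand-in for more principled scale selection.
- MLR importance is exactly zero-information about coefficient
  uncertainty: no p-values or intervals are computed.
- The pipeline's byte-identical determinism holds for fixed package and
  dependency versions; floating-point differences across BLAS builds can
  change trailing digits.
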