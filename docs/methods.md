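# Methods

## Overview

`pcpselect` identifies a small, interpretable set of amino-acid property
indices (physicochemical/biochemical scales such as hydrophobicity, helix
propensity, net charge) that discriminates two classes of protein sequences —
the motivating application being DNA-binding versus non-binding
domains/proteins.  The pipeline has four stages:

1. **Property clustering.**  Each index is a 20-vector (one value per
   standard residue).  Profiles are z-normalized per index (mean 0,
   population SD 1) and clustered with fuzzy c-means so that near-duplicate
   scales — of which the AAindex collection has many — land in the same
   cluster.
2. **Sequence encoding.**  A sequence of length *l* paired with an index
   yields an *l*-profile; its mean is the feature (a composition statistic).
   With *m* selected indices a sequence becomes an *m*-vector, min-max
   scaled per column to [-1, 1].
3. **Feature selection.**  An inheritable combinatorial GA (IBCGA) searches
   subsets of exactly *r* indices jointly with two 4-bit SVM
   hyper-parameter genes, using pooled 5-fold cross-validated accuracy of
   an RBF SVM as fitness, for *r* = r_start … r_end in one run via
   inheritance.  R independent runs quantify selection stability.
4. **Ensemble analysis.**  Appearance frequencies f(p) over the R runs give
   each run's robustness score S_t = mean f over its features; reports
   cover the accurate pick S_a (highest fitness), robust pick S_r (highest
   score), main-effect-difference (MED) feature ranking, per-cluster
   selection frequencies, a replacement scan for interchangeable
   near-duplicate properties, and a compact one-feature-per-cluster set.

## Models and algorithms

### Fuzzy c-means (fcm)

Minimizes J = Σ_i Σ_j u_ij^s d(v_i, x_j)² with Euclidean d by alternating
updates; memberships are column-stochastic, the objective is non-increasing,
and a point coincident with prototypes receives full membership there.
Initialization is a seeded random membership matrix.  Defaults: fuzzifier
s = 1.12 and K = 20 clusters, a calibration recommended for exactly this
kind of z-scored profile data (larger s with only 20 dimensions drives all
memberships toward uniformity); tol = 1e-6 on the max membership change,
max_iter = 500.  Cluster ids are canonicalized by decreasing size, ties by
smallest first-member index, so labels are stable across reruns; with
separated data this makes different seeds produce identical labelings.

### SVM evaluation (svm_eval)

RBF kernel throughout — the chromosome encodes a kernel width γ, which only
makes sense for an RBF-type kernel.  γ, C ∈ {2^-7 … 2^8} (the 16-value,
4-bit-encodable grid; decode is 2^(code-7)).  Cross-validation is
stratified and seeded; the confusion matrix is pooled over folds
(micro-average), so accuracy is a single correct/total ratio.  MCC is 0
when a denominator factor vanishes.

The GA's fitness oracle (`ibcga.feature_subset_fitness`) computes the same
pooled 5-CV accuracy from cached per-feature squared-difference matrices
(the subset Gram matrix is exp(-γ Σ_j D2_j)) through the low-level libsvm
binding; a test asserts exact agreement with `svm_eval.cv_fitness`.  This
matters because one selection run makes 10³–10⁴ subset evaluations.

### IBCGA (ibcga)

Chromosome: n binary genes with exactly r ones, plus the two 4-bit
parameter genes.  Every operator preserves popcount r:

* init — r ones placed uniformly at random;
* OA crossover — gene positions are split into `oa_factors` contiguous
  blocks (default 5); blocks plus the two parameter genes are two-level
  factors (take from parent 1 or 2) of a Sylvester-type strength-2
  orthogonal array (7 factors → L8, 8 evaluations per crossover).  Each OA
  row's candidate is repaired to popcount r by random compensating flips
  and evaluated; children are the best candidate and the "reasoned"
  combination of each factor's better level (by main effect);
* mutation — swap one selected/unselected pair and resample one parameter
  gene; never applied to the generation's best individual;
* inheritance — every individual flips one random 0→1 when moving from r
  to r+1.

Selection is binary tournament with replacement.  Elitism keeps the
best-ever chromosome in the population.  Stopping: `stop_idle` generations
without improvement (default 10) or `max_gen` (default 60).  Defaults
follow the search-size conventions of the method family: r from 10 to 30,
population 50, p_c = 0.8, p_m = 0.05, R = 30 runs.

**Fold handling.**  Within one generation every chromosome is evaluated on
the same stratified 5-fold split; between generations the folds are
redrawn from the run's seeded stream.  A single fixed split for a whole
run lets the search overfit that split (we observed nominal fitness 0.97+
from uninformative features before adopting per-generation folds); redrawn
folds make only persistently useful features survive.  A consequence is
that recorded best fitnesses are maxima over fold draws and thus
optimistically biased — the acceptance script therefore re-evaluates the
chosen solution on fresh folds for its reported accuracy.

### MED ranking

The m features of a solution are two-level factors (kept/removed) of an OA
over m columns; each row's kept-subset is evaluated, and MED_j is the
absolute difference of mean fitness with j kept vs removed.  Rank 1 is the
largest MED; ties break lexicographically.  On additive fitness this
reproduces the exact per-feature weights (tested against a full-factorial
oracle).

### Ensemble analysis (ensemble)

Each run contributes its best-fitness X_r (ties to smaller r, preferring
parsimony).  f(p) = share of runs whose set contains p; S_t = mean f over
the t-th set; S_a / S_r as above, ties to the smaller run index.  The
replacement scan examines every property P1 outside the selected set
against every selected P2 within z-space distance d_max (default: 5th
percentile of all pairwise distances) and flags P1 as promising when
swapping it for P2 costs at most `acc_drop_max` accuracy (default 3
percentage points).  The compact per-cluster set is found by exhaustive
enumeration when the categorical space has ≤ 64 combinations (parameter
codes held at γ = C = 1) and otherwise by the same OA-reasoned GA machinery
over categorical genes.

## Synthetic benchmark (synthetic)

The generator produces the two planted structures the pipeline is tested
against.

**Property table.**  `n_clusters` standard-normal centroids in 20
dimensions; non-informative properties are centroid + N(0, spread²) noise,
dealt round-robin.  Properties declared *informative* get independent
standard-normal profiles of their own (singleton clusters): if informative
properties shared centroids with 0.99-correlated decoys, feature-level
recovery would be ill-posed — any member of the cluster would be an equally
valid "recovery".  Cluster-recovery tests use `informative=()` for the pure
clustered table.

**Sequences.**  Residues are i.i.d. draws from class-specific compositions
p₀ ± dp/2 (base p₀ uniform by default; a Swiss-Prot-like option exists),
lengths uniform on `len_range`.  The shift dp solves a linear program:
every informative property's between-class difference in expected z-profile
mean equals the planted effect exactly, the worst-case mean-leakage onto
any non-informative property is minimized, and both compositions stay on
the simplex.  Some leakage is unavoidable (20 dimensions cannot be
orthogonal to ~55 decoy profiles), but the LP keeps it roughly an order of
magnitude below the planted effect.  Earlier designs were rejected for
measurable pathologies: a smooth exponential tilt leaked ~60 % of the
effect onto decoys, and an unbounded LP drove some residue probabilities
to extremes that the RBF SVM could exploit through distribution shape; the
bounded LP (|dp_i| ≤ 2 p₀ᵢ with leak minimization) shows decoy-only CV
accuracy ≈ 0.55 against 0.93 for the planted subset.

**Effect-size units.**  A length-L sequence contributes feature noise of SD
≈ sd(property)/√L, so a fixed composition shift has a statistical size that
depends on L.  `effect_size` is calibrated in units of the per-sequence
feature SD at the reference length (midpoint of `len_range`): effect 1.2
means class means 1.2 feature-SDs apart — one informative feature supports
~73 % accuracy, five jointly ~91 %.  Expressing the effect in raw profile-SD
units instead would make any detectable effect ~10σ at typical lengths
(every subset saturates at accuracy 1.0) or infeasible on the simplex;
feature-SD units keep the planted problem learnable but unsaturated, which
is what a selection benchmark needs.  In raw terms the planted difference
is effect_size/√L_ref profile SDs.

**Second-moment leakage.**  The LP controls *mean* differences only.  A
composition shift also perturbs the covariances of the per-sequence
features, and unlike means this perturbation is a relative effect not
damped by sequence length, so with enough sequences an RBF SVM can extract
class signal from joint distributions of nominally uninformative features.
On the default table the effect is minor (decoy-only accuracy ~0.55 against
0.93 for the planted subset), but on some table draws specific decoy
*combinations* reach 0.8–0.9.  We evaluated two remedies — adding
covariance-perturbation rows to the LP, and per-class composition jitter
whose between-sequence covariance compensates the within-sequence
difference — and kept neither: both reduced the leak inconsistently across
table draws while distorting the mean-effect calibration.  The planted
recovery experiment is therefore defined on the default (seed 0) table,
and recovery counts on other tables should be read with this caveat.

**What the generator does not emulate:** real binding biology (motifs,
position effects, structural constraints), residue autocorrelation within
sequences (draws are i.i.d.), class imbalance, and homology structure
between sequences.  Passing the planted-recovery suite shows the search
machinery retrieves composition-level signal at realistic noise; it says
nothing about performance on real proteomes.

## Study conditions used by the test suite and acceptance script

Default synthetic conditions: 60 properties in 6 clusters (spread 0.1),
5 informative, effect 1.2, 100+100 sequences of length 50–150.  The
planted-recovery scenario runs the reduced ensemble the conditions call
for — r = 3…8, population 30, R = 5 runs — with stopping limits
stop_idle = 2, max_gen = 6; at these sizes each run converges within a few
generations and one ensemble takes tens of seconds on one CPU, so the
10-master-seed recovery experiment stays within a routine test-suite run.
The GA-optimality check uses 15 properties, r = 4 (C(15,4) = 1365 subsets,
small enough for the exhaustive oracle) with a fixed fold split so the
optimum is well-defined.

## Numerical choices and edge cases

* z-scoring uses the population SD (÷20); constant profiles map to all
  zeros rather than NaN.
* Min-max scaling maps constant columns to 0; held-out values are clipped
  to [-1, 1].  Scaling is fit on the full training set (global
  normalization); fitting within CV folds is available via
  `svm_eval.make_folds` + per-fold scaling but is not the default.
* Ambiguous residues (X, B, Z, U, O, gaps) are dropped before averaging; a
  sequence with no standard residues is rejected.
* Nearest-neighbour group assignment breaks ties by lexicographically
  smallest labeled accession.
* FCM singularities (point on prototype) get full membership split among
  the coincident prototypes.
* The GA repairs popcount violations by random compensating flips from the
  run's seeded stream; all randomness flows from one master seed per run
  (child seeds < 2³¹).

## Known limitations

* Recorded GA fitnesses are optimistically biased (max over fold redraws);
  use fresh-fold re-evaluation for honest accuracy, as the acceptance
  script does.
* The L=1 (profile mean) encoding discards all positional information by
  construction.
* `per_cluster_select`'s exhaustive path fixes the SVM parameter codes at
  their defaults; only the GA path searches them.
* Appearance-frequency scores treat feature sets as unordered; two runs
  selecting different members of one tight cluster count as disagreement
  even though the selections are functionally equivalent (the cluster
  frequency report exists precisely to surface this).
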