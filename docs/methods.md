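# Methods

## The NN digraph and its summaries

Every point is assigned exactly one nearest neighbor (Euclidean distance
on planar coordinates, or any symmetric dissimilarity with minimal
diagonal).  Ties are broken to the lowest point index by default — the
deterministic choice matters for grid-recorded field data, where exact
ties are common; a seeded random tie-break is available.  Duplicate
(zero-distance) points are allowed with a logged warning.  No edge
correction is applied anywhere: near a window boundary the NN relation
is taken at face value, which makes the tests slightly liberal or
conservative for stochastic-window data.

The digraph summaries that the RL moments condition on:

* in-degree counts Q_j (number of points serving as NN exactly j times);
* Q = 2(Q₂ + 3Q₃ + 6Q₄ + 10Q₅ + 15Q₆) = Σ j(j−1)Q_j, the number of
  ordered pairs of distinct points with a common NN;
* Q̃ = 2 Σ C(j,2) Q_j over *all* observed j — identical to Q for planar
  Euclidean data (j ≤ 6), relevant only for general dissimilarities;
* R = twice the number of reflexive (mutually nearest) pairs.

Q_j is stored for all observed j, uncapped, so dissimilarity inputs with
hub points are handled exactly.

## Random-labeling moments and the covariance completion

Under random labeling the class labels are a uniformly random
arrangement over the fixed digraph, so every NNCT cell N_ij is a sum of
indicators over the n out-arcs.  The probability that an ordered tuple
of distinct points carries given classes is a ratio of falling
factorials (e.g. p_ij = n_i n_j / (n(n−1))); the exact expectation is
E[N_ij] = n·p_ij = n_i n_j/(n−1), with n_i n_j/n the familiar large-n
value.

Second moments are assembled by classifying ordered pairs of arcs into
six coincidence classes with counts

    same arc: n;  reflexive pair: R;  shared target: Q;
    head-to-tail chains: n − R each;
    all four points distinct: n² − 3n − Q + R,

each weighted by the tuple probability of the points involved under the
label-compatibility constraints.  This single computation reproduces the
closed-form Var[N_ij] and Cov[N_12, N_21] exactly and supplies all six
covariance cases of the multiclass Σ_sym.  When the two index pairs
involve four distinct classes, the four raw covariances entering
Cov[N_ij − N_ji, N_kl − N_lk] coincide and the difference covariance is
exactly zero (the raw cell covariances themselves are not individually
zero).  The implementation is validated to 10⁻¹² against exhaustive
enumeration of all labelings on patterns with n ≤ 8 across class splits
(`rl_enumeration_oracle`, exact integer arithmetic).

For the quartet term the exact p_iijj is used throughout; a published
variant writes p_ii·p_jj at one point, which is only its large-n
approximation and does not match the enumeration oracle.

The overall statistic X²_D = T_S′ Σ_sym⁻ T_S uses `scipy.linalg.pinvh`
with relative eigenvalue tolerance 1e−10; the degrees of freedom equal
the numerical rank (k(k−1)/2 when non-degenerate).  T_S is ordered
lexicographically by (i, j), i < j, in first-appearance class order.
Under CSR the observed Q and R are plugged in, making the test
conditional on the realized digraph.  Degenerate digraphs exist: a
perfect matching (every point in a reflexive pair) gives
Var[N_12 − N_21] = 0 exactly, and the test raises an error rather than
return a meaningless value.

## The Q-symmetry table and its tests

The full table records in-degrees 0..5 with overflow pooled into the
last column.  The default reduction merges all columns m ≥ 2 (k×3,
df 2(k−1)); this fixed rule, rather than the adaptive expected-count
criterion (also provided), is the default because it is the form used in
every published analysis the fixtures reproduce.  The Pearson statistic
uses expected counts n_i Q_m / n; a subscript typo in one published
statement of this formula (n_j for n_i) is resolved in favor of the
row-sum × column-sum / total convention, which reconciles every printed
chi-square.  Zero-total columns are dropped with a warning and the df
reduced.

Exact conditional inference fixes both margins, giving each table the
multiple hypergeometric probability, computed in log space via
`gammaln`.  For 2×c tables the enumeration over the c−1 free entries of
row one is vectorized; general r×c tables use depth-first composition
generation with margin pruning and a 10⁷-table cap, beyond which a Monte
Carlo mode samples the fixed-margin null by random pairing of row and
column labels.  Probability ties are compared with relative tolerance
1e−12 so equal-probability tables enter the inclusive sum as the
definition requires.  The twice-table-inclusive value is capped at 1.
The Tocher decision draws its uniform variate from the seeded generator
and reports it; outside the randomization window (p_exc < α < p_inc) the
table-inclusive value is returned, preserving the ordering chain
p_exc ≤ p_Toc ≤ p_inc ≤ p_t,inc.  For tables with more than two rows the
exact machinery is an extension beyond its published two-row use and is
flagged as such here.

## Sampling frameworks and the conservativeness warning

McNemar/Bowker and the exact binomial version treat base–NN pairs as
independent trials, which holds (approximately) only for sparsely
sampled pairs.  Completely mapped data violate it — reflexive pairs
alone introduce strong dependence — and the tests then reject far below
nominal level (empirical size below 10⁻² at α = .05 in the CSR harness).
Every result object from this family carries a standing warning and the
recommended alternative: the label-randomization p-value, which permutes
class labels over the fixed geometry and ranks the observed statistic,
p = (1 + #{T_b ≥ T_obs})/(B + 1).

## Simulators

All generators live on the unit square and are seed-deterministic.

* **CSR independence**: both classes iid uniform, sizes fixed.
* **RL backgrounds**: uniform, or Matérn cluster (parents Poisson(κ) in
  the square, offspring counts Poisson(μ), offspring uniform in discs of
  radius r, no clipping); realizations with n < 4 are redrawn and
  logged.  The RL harness default follows the published protocol of 100
  backgrounds × 1000 relabelings.
* **Case I**: Y bivariate normal around the center, sd σ (default 1/10).
* **Case II**: each Y attached with probability p to a uniformly picked
  X (with replacement), displaced by a uniform radius up to that X's NN
  distance among the X points at a uniform angle; otherwise uniform.
  The "minimum distance" in the published description is read as the
  picked point's NN distance — the global minimum makes the attachment
  degenerate (coincident points) and produces *less* asymmetry, not
  more.
* **Case III**: shifted supports (0,1−s)² vs (s,1)².
* **Case IV**: half of each class iid on its support, the other half at
  fixed radius r and uniform angle from its partner (even class sizes
  required); displaced points may leave the square — no clipping.
* **Case V**: Y_j at fixed radius r from X_j (requires n₂ ≤ n₁).
* **Case VI**: backbone of m₁+m₂ uniform X points with NN distances
  d_i; Y_i = X_i + U(0, ρd_i)·(cos θ, sin θ) for i ≤ m₁; an extra X′
  attached the same way to each of the last m₂ backbone points; the
  remaining 2m₂ Y points uniform.  Class sizes n₁ = n₂ = m₁ + 2m₂.  The
  published three-stage text instead jitters the last m₂ Y points off
  the uniform ones, but taken literally that construction collapses into
  a perfect matching at small ρ (Q = 0, Z_D undefined) and its moments
  contradict the published ones; the form implemented here reproduces
  the published N_12, N_21 means, SDs and rejection rates across all
  three published ρ values.  See the limitations note below.

The empirical-rate harness uses the asymptotic critical values
(statistic above the χ²/normal 1−α point; exact tests via p < α),
matching the published estimator, and reports binomial Monte Carlo
standard errors and the N_12, N_21 summaries.

What these simulations do *not* emulate: inhomogeneous intensity,
interaction (Gibbs) structure, measurement error in coordinates, and
window edge effects beyond what falls out of the generators themselves.
Passing size/power checks therefore demonstrates correctness of the
statistics under the stated designs, not robustness on arbitrary field
data.

## Problem sizes used in the checks

The test suite estimates the CSR sizes at N_mc = 10000 (two classes of
50) and the alternative-pattern powers at N_mc = 2000; the
reproduction script uses N_mc = 10000 throughout.  The moment constants
E[Q/n] ≈ .63 and E[R/n] ≈ .62 are checked on 50 uniform patterns of
n = 1000.

## Known limitations

* One published simulation table for the Case II pattern could not be
  reproduced under any reading of its construction tried here (its
  printed mean N_12 = 45.3 exceeds the class size 40, and its printed
  rejection-rate combination is internally inconsistent with the RL
  variance framework); the Case II generator implements the literal
  description, and its power for the shared-NN test at p = .75 is about
  .08, far below the published .99.
* The published two-class McNemar/Bowker statistics for the worked
  forestry example do not follow from the printed contingency tables
  (direct evaluation gives 6.853 uncorrected vs 6.182 printed); the
  raw coordinates needed to adjudicate are not bundled, so only the
  Q-symmetry chi-squares — which reconcile exactly — are asserted
  against published values.
* One published one-versus-rest Q-symmetry table has an inconsistent
  row margin; it ships as printed alongside a corrected variant (148 →
  143, the unique value restoring both margins), and the corrected
  variant reproduces the published statistic 16.125.
* Exact tests for k > 2 rows and dissimilarity-defined NN relations are
  extensions beyond their published scope, flagged in their docstrings.
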