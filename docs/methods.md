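# Methods

## The analysis model

The package treats a cohort as n subjects × K binary condition indicators,
with a sex stratum and a strictly positive survey weight per subject. All
probability estimates (margins, supports, confidences, triad prevalences)
are survey-weighted proportions by default, so they estimate population
quantities; the `unweighted` mining mode is available for auditing. The
sample size n entering the 1/n term of the standardised-lift lower bound is
always the *unweighted* respondent count of the stratum — it encodes the
granularity of observable supports (the smallest nonzero support is one
person), which weights do not change.

### Standardised lift

For single-condition sets the lift P(A,B)/(P(A)P(B)) is 1 under independence,
but its attainable range depends on the margins: it can never exceed
1/max{P(A),P(B)} (since P(A,B) ≤ min{P(A),P(B)}), and for a rule that is
mineable at all it cannot fall below
max{P(A)+P(B)−1, 1/n, s, c·P(A)}/(P(A)P(B)), where s and c are the support
and confidence floors (both 0 by default — interactions of rare conditions
are of interest, so no lower limit is imposed). The standardised lift is the
affine rescaling of the lift onto [0, 1] by these bounds.

Two upper-bound conventions circulate: the attainable bound
υ = 1/max{P(A),P(B)} and a looser, formula-only bound υ = 1/(P(A)P(B)).
The package defaults to the attainable bound (`corrected`) because it is the
only one consistent with the published worked value for the female
hypertension/high-cholesterol pair (0.4261, 0.5231, joint 0.262, n = 3347 →
0.615, printed as 0.61; the loose bound gives 0.26). The loose variant is
kept behind `upper_bound_variant="as_printed"` purely for auditability, and
a regression test pins down the asymmetry.

**Definedness.** A rule is *defined* (mineable) only when both margins are
strictly inside (0, 1), the observed support is at least the lower-bound
numerator (in particular ≥ 1/n: the pair co-occurs in at least one subject,
and clears the configured floors), and υ − λ ≥ 1e−12. This is what makes the
bound guarantee λ ≤ lift ≤ υ and std_lift ∈ [0, 1] a theorem rather than a
tendency: a zero-support pair is not a rule, and treating it as one would
produce a negative standardised lift. Undefined combinations are carried as
flagged records (never exceptions) so full K×K outputs keep their shape.

**A structural property worth knowing.** For an exactly independent pair the
standardised lift is approximately max{P(A), P(B)} (lift = 1, λ ≈ 0,
υ = 1/max), *not* 0. A fixed retention threshold t therefore keeps every
independent pair whose larger margin exceeds t; only below that prevalence
is retention driven by sampling noise. This explains why prevalence-rich
cohorts retain many hundreds of the K(K−1) possible rules at t = 0.2, and it
dictates the design of the parameter-recovery experiment (below).

### Triads

The standardised lift is defined for a pair of events; for a triple
{X, Y, Z} the package scores the six bipartition rules {X} ⇒ {Y,Z} and
{Y,Z} ⇒ {X} (margins being set-event probabilities) and reports the maximum.
This choice is symmetric in the triple, reduces to the pairwise definition
in the degenerate case, and attains 1 for three mutually comonotone
conditions. Only triples observed together in at least one subject are
enumerated; a reporting filter keeps qualifying triads with weighted
prevalence above 5% (configurable).

### Sex association testing

Each condition is tested against sex with the 2×2 chi-square statistic on
unweighted counts, 1 df, no continuity correction (stratum sizes in the
thousands make the correction immaterial), followed by Benjamini–Hochberg
adjustment across the K conditions at q < 0.05. Prevalences are reported
weighted while the test uses raw counts: a design-corrected (Rao–Scott
style) test is deliberately out of scope, and both counts and weighted
proportions are emitted so either convention can be audited. Conditions with
zero variance are recorded as not-tested rather than aborting the run.

### Networks and communities

Retained rules (either direction) define one undirected edge per condition
pair; the edge weight is the unweighted number of stratum participants with
both conditions (matching the plotting convention that edge width counts
people) and the node attribute is the weighted prevalence. Community
detection is agglomerative greedy modularity maximisation
(Clauset–Newman–Moore): starting from singletons, repeatedly merge the pair
of communities with the largest ΔQ, track the full merge history, and return
the partition at peak Q. Newman's weighted modularity
Q = Σ_c [W_c/W − (S_c/2W)²] is implemented directly (and cross-checked
against networkx in the tests); ΔQ ties are broken by the lexicographically
smallest community labels so results are identical across platforms.
Modularity uses the co-occurrence edge weights by default with an unweighted
flag, since the weighting convention used in published comorbidity
clusterings is usually unstated.

## Synthetic cohorts

The generator draws, per stratum, latent vectors Z ~ N(0, R) and sets
indicator k to 1 when Z_k exceeds the standard-normal upper-tail quantile of
margin p_k, so E[indicator] = p_k exactly. R must be symmetric with unit
diagonal; eigenvalues in [−1e−8, 0) are clipped to 0 (floating-point slack
for user-entered matrices), anything lower is rejected naming the offending
eigenvalue. The exact joint probability of a pair is the bivariate-normal
orthant probability, computed by reducing to the one-dimensional integral
∫_a^∞ φ(x) Φ((ρx−b)/√(1−ρ²)) dx with adaptive quadrature (abs. tolerance
1e−13); the test suite verifies it against an independent two-dimensional
Gauss–Legendre quadrature of the raw density and against Monte-Carlo
integration at n = 10⁷. `calibrate_dependence` inverts the orthant function
by monotone bisection (60 iterations, |f| < 1e−10), so tests can plant a
pair with any chosen lift.

Weights are log-normal with unit mean and dispersion σ = 0.3 (strictly
positive and right-skewed, the generic shape of survey weights; the true
weight distribution of the motivating survey is not published, so this is a
stand-in, not an estimate), rescaled to stratum mean exactly 1.

`aging_cohort_spec()` is a ready-made two-stratum specification emulating a
population-representative health survey of adults aged 50+: 2,754 men and
3,347 women, 31 self-reported chronic conditions with per-sex margins from
0.15% to 52.31%, and a latent three-group factor structure (general frailty
0.35 on all conditions; cardiovascular 0.40; cardiometabolic and
musculoskeletal/endocrine 0.35 each) that plants realistic positive
dependence — e.g. a latent correlation of ≈0.25 between hypertension and
high cholesterol, which reproduces a female joint prevalence of ≈26% and a
standardised lift of ≈0.6. Factor loadings keep R = LLᵀ + diag(1−‖l‖²)
positive semidefinite by construction.

**What the generator does not emulate:** the survey's sampling design and
non-response adjustment (weights are consumed, not derived), questionnaire
skip patterns, higher-than-pairwise calibrated dependence (triads inherit
dependence from the pairwise latent structure), and any longitudinal
structure. Passing tests therefore demonstrate correctness of the estimators
and the mining logic under a Gaussian-copula dependence model — not that the
method's published substantive findings hold in any real cohort.

## Validation design and problem sizes

- **Oracle equivalence** is checked on 6–12-subject cohorts against
  exhaustive subset counting, and community detection against brute-force
  search over all set partitions of ≤ 8 nodes (Bell(8) = 4140 partitions).
- **Bound properties** are verified exhaustively over every 2×2 contingency
  table with total count n ≤ 40 (~1.2×10⁵ tables) plus randomised tables up
  to n = 200 via hypothesis.
- **Parameter recovery** plants one calibrated pair (margins 0.12/0.15,
  lift 3 → std lift ≈ 0.45) among six independent background conditions with
  margins 0.04–0.08, two strata of 5,000 subjects, 50 seeds. All margins sit
  below the 0.2 threshold deliberately: given the structural property above,
  any condition more prevalent than the threshold would drag its independent
  partners over it by construction, and the experiment is meant to measure
  noise-driven false retention, not that known bias.
- **FDR control** is checked under a global null (20 conditions independent
  of sex, 250 subjects per stratum, 500 replicates): the fraction of
  replicates with any q < 0.05 discovery must stay ≤ 0.07 against the
  nominal 0.05.
- The end-to-end pipeline is required to be byte-identical across repeated
  runs at fixed seed and configuration.

## Known limitations

- The chi-square sex test ignores the survey design; with strongly
  informative weights its nominal level is approximate.
- Greedy modularity maximisation is a heuristic; on small graphs the tests
  compare it to the exhaustive optimum and report (never hide) any gap.
- The triad score is an interpretation — published analyses rarely state
  which rule form a triplet's standardised lift refers to; the bipartition
  maximum used here is one defensible symmetric choice.
- The `as_printed` upper-bound variant can exceed the attainable lift range
  and is provided only to reproduce formula-literal computations.
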