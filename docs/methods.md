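# Methods

## The likelihood

The data are a set of independent pedigrees (singletons are one-member
pedigrees).  A diallelic trait locus with alleles D (predisposing) and d is
tested against one genotyped marker with k codominant alleles.  The latent
state of individual *i* is an ordered pair of two-locus haplotypes
(paternal, maternal), each haplotype `(a, m)` with `a ∈ {D, d}` and
`m ∈ {1..k}` — `4k²` states per person.  The pedigree likelihood is

```
L = Σ over all members' ordered genotypes of
    Π_founders  P(h_pat) P(h_mat)              (Hardy-Weinberg haplotype prior)
  × Π_children  T(h_pat | father) T(h_mat | mother)   (transmission)
  × Π_members   pen_i                          (phenotype x marker typing)
```

with the transmission kernel assigning probability `(1-θ)/2` to each intact
parental haplotype and `θ/2` to each recombinant.  The penetrance factor is
`f_c` for affecteds, `1 - f_c` for unaffecteds (c = copies of D carried) and
1 for unknown phenotype, times an indicator that the typed marker genotype
(if any) equals the state's unordered marker pair.  A genotype with one
missing allele is treated as fully missing; no partial-typing information is
used.

**Assumptions.** Hardy-Weinberg equilibrium and independence of a founder's
two haplotypes; random mating; no sex-specific recombination, imprinting,
liability classes or X-linked transmission; phenotype conditionally
independent of the marker given the trait genotype.  Trait-model parameters
(`p_D`, penetrances) are fixed inputs, never estimated: the free parameters
are the marker allele frequencies (one simplex, or two conditional
simplices under LD) and θ under linkage.  Because all four hypothesis
models share the fixed trait model, phenotype-based ascertainment
(affected sib pairs, cases, controls) contributes a factor that cancels in
every likelihood ratio.

## Computation

**Peeling.**  `peel_loglik` runs variable elimination over individuals in a
leaves-upward order (the Elston-Stewart scheme): children without
descendants are absorbed into their parent couple with two `(4k² × 2k)`
matrix products; remaining individuals (connectors between nuclear
families) are eliminated by generic sum-product contraction in a min-size
order.  Every elimination rescales the resulting factor by its maximum,
accumulating the log-scale, so sibships of any size cannot underflow.
Marriage loops are detected on the individual-mating incidence graph;
looped pedigrees are not peeled but fall back to bounded brute-force
enumeration (default cap 1e8 states).

**Oracle.**  `enumerate_loglik` materialises the full joint state tensor
(`(4k²)^n`) by broadcasting the same factors and sums it — exponential, but
algorithmically independent of the peeling order and valid on loops.  The
test suite keeps randomized-pedigree sizes within `(4k²)^n ≤ ~2e7`
(6 members at k = 2, 4 at k = 3, 4), and requires agreement to 1e-9
relative across all four hypothesis models.

**Collapsing.**  For model fitting, pedigrees with identical structure,
phenotypes and marker genotypes are grouped, penetrance vectors are
precomputed, and one likelihood evaluation costs a few small matrix
products per *unique* pattern.  Simulated replicates (hundreds of nuclear
families drawn from a handful of genotype configurations) evaluate in
about a millisecond.

## Optimization

Likelihoods are maximized by a MADS variant in box-scaled coordinates
(every parameter mapped to [0, 1]; θ from [0, 0.5]):

* **Poll.**  2n directions per iteration: the columns of the integer
  scaled-Householder matrix `‖q‖²I − 2qqᵀ` of a pseudo-random integer
  vector q, and their negatives.  The columns are exactly mutually
  orthogonal, and as the mesh refines the normalized direction set
  densifies on the unit sphere.  Polling is opportunistic (stops at the
  first improvement).
* **Mesh.**  Mesh size `δ = min(Δ, Δ²)` for poll size Δ (initial 1.0).  Δ
  halves after a failed poll and is **kept** after a success.  Re-expanding
  after successes (a common textbook choice) was evaluated on a tuning set
  of simulated likelihood problems and cost ~30% more evaluations — every
  re-expansion must later be paid back with one full failed poll per extra
  level — without improving the optima found; the non-increasing update is
  therefore the default.  Termination when Δ < 1e-4 (so the largest
  proposed parameter change is below 1e-4) or on the evaluation budget.
* **Search.**  Before polling, a quadratic model is least-squares fitted to
  recent evaluations and its constrained maximizer (Newton point when the
  fitted Hessian is concave, else a gradient step), clipped to the box and
  a trust region of 2Δ, is evaluated — unless the model predicts no
  improvement, in which case the evaluation is saved.
* **Constraints.**  Box bounds are enforced by construction (trial points
  are clipped then snapped to the mesh toward the incumbent).  The simplex
  constraints are handled by the extreme barrier: the last frequency of
  each simplex is implicit, and any trial point whose implicit entry leaves
  [0, 1] is reported infeasible and can never become the incumbent.  This
  keeps boundary MLEs (frequencies exactly 0 or 1, which occur routinely)
  reachable — a logit-type reparameterisation would push them to infinity.
* **Reproducibility.**  One seeded generator drives the poll directions;
  with a fixed seed the full trace is bit-reproducible.  An evaluation
  cache avoids re-evaluating revisited mesh points.

The GPS comparator polls the fixed directions `{±eᵢ}` with the same
halving schedule and restarts from its own solution at full step size
until no improvement, mirroring how pattern search was historically
deployed to reduce stalling; MADS is invoked once per problem.  On the
12-problem benchmark battery (`linkld.benchmark`) MADS reaches the best
known optimum within 1e-4 using fewer total evaluations.

## Hypothesis tests

Models are fitted in nesting order.  Every larger model starts from the
best of (a) the moment start — observed allele frequencies, θ₀ = 0.25,
conditional simplices both at the observed frequencies — and (b) the
smaller models' solutions embedded exactly (θ = 0.5 and/or equal
conditional frequencies reproduce the smaller model's likelihood
bit-for-bit).  Since the optimizer never returns less than its starting
value, `2(logL_alt − logL_null) ≥ 0` structurally; a failed maximization
can cost power but can never produce a negative statistic or an
inconsistent numerator/denominator pair.

**Null distributions.**  The tests that free only θ (linkage; linkage given
LD) put the null on the boundary θ = 0.5: their statistic has an atom at
zero (θ̂ = 0.5 in roughly half of null replicates) and the default p-value
is the classical 50:50 mixture `½χ²₀ + ½χ²_1`.  The joint test frees θ
together with the conditional frequencies; in 300-replicate null
calibration runs (θ = 0.5, linkage equilibrium, 100 ASP families + 200
singletons, fully penetrant dominant model) its statistic showed *no* atom
at zero — the frequency parameters always absorb some deviance — and both
the `½χ²₀+½χ²_df` and the boundary-theory `½χ²_{df-1}+½χ²_df` references
were anti-conservative (empirical α 0.093 and 0.083 at nominal 0.05),
while plain `χ²_df` was calibrated (α 0.057, within binomial noise of
0.05).  The joint test therefore defaults to plain chi-square;
`chi2_mode="plain"` forces plain chi-square everywhere, and the
`boundary_adjusted` flag records what was used.  Degrees of freedom are
free-parameter differences (k = 2: linkage 1, LD given linkage 1, joint 2).
P-values are per marker; no multiple-testing correction is applied.

## Two-stage screening

For many markers, stage one computes (a) the HHRR chi-square comparing
marker alleles transmitted vs untransmitted by genotyped parents to
affected offspring (ambiguous fully-heterozygous transmissions are skipped
to keep integer counts; pure case-control data fall back to an
affected-vs-unaffected allele-count table) and (b) the 1-df linkage LR
test.  A marker proceeds to the full battery when either p-value passes
its loose threshold (defaults 0.05/0.05, OR-combined — a screen should be
permissive).  Raising either threshold can only grow the pass list.

## Simulator

`simulate_dataset` gene-drops datasets with known truth: founders draw
haplotypes from the design's (conditional) frequencies, children are
formed by seeded meioses with recombination θ, phenotypes follow the
penetrances, and ascertainment (affected sib pairs, affected cases,
unaffected controls, ...) is enforced by rejection sampling with a 1e6
attempt cap — exact for such rules, though designs demanding near-zero
probability events fail loudly rather than bias the sample.  Missingness
is applied last, per individual class.  Randomness is one root seed with
per-family spawned streams, so datasets are bit-reproducible and
individual families independent of family count.  Default study designs
follow the sib-pair/case-control mixtures used throughout the tests
(e.g. 100 ASP families + 200 singletons per null replicate; 200 ASP
families for recovery; batteries of 30-50-family problems for the
optimizer comparison) — sizes chosen so each battery completes in minutes
on one CPU while keeping binomial noise on calibration estimates a few
times smaller than the effects being checked.

**What the simulator does not emulate:** genotyping error, population
stratification, locus heterogeneity, phenocopies under the extreme models,
missingness that is informative, and real LD decay across many markers.
Passing tests therefore demonstrate internal correctness and calibration
under the stated model, not robustness to those real-data complications.

## Numerical choices and edge cases

* Monomorphic markers (fewer than two observed alleles) are rejected with
  an explicit error, never fitted.
* Marker allele codes are taken as 1..k with k the largest observed code.
* Impossible data under a model (e.g. an affected child of two unaffected
  parents under full penetrance) yield −∞ log-likelihood, flagged, and an
  explicit error if no feasible starting point exists.
* Mendelian checking is per nuclear family; untyped parents range over
  alleles observed in the family (sufficient: an unobserved allele can
  never be required for a transmission to a typed child).  Inconsistencies
  spanning several generations may be missed, as they are by most tools.
* `p = 1` is reported at statistic 0 (the atom), for every convention.
* The implicit simplex member is the **last** allele's frequency.

## Known limitations

Looped pedigrees only via bounded enumeration; single-marker (two-point)
likelihoods only; no liability classes or quantitative traits; no
permutation p-values; the boundary-mixture calibration finding above was
established for the rare-allele extreme models and k = 2 and may differ
for common-allele models or highly polymorphic markers.
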