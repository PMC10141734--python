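# Methods

This note records the statistical procedures implemented in
`rearingnet`, the modelling assumptions behind the synthetic-survey
generator, and the numerical and design choices that were genuinely
open, in enough detail that any reported number can be re-derived.

## Data model

The atomic observation is one weighed resource fragment (a *sample
unit*) monitored for fly emergence, with per-species counts of emerged
adults. Zero counts are implicit: stored emergence rows always mean "at
least one fly", which keeps the binary breeding-record view of the
interaction matrix (`count ≥ 1`) unambiguous. Plant taxa carry a
geographic origin (neotropical `N`, exotic `E`, or `EN` for
mixed-parentage hybrids) and a resource-type code (FF fleshy fruit, DF
dry fruit, SB stem bulb, ST stem tuber, RT root tuber, VL leaves);
flies carry a strictly binary N/E origin. Named varieties are distinct
taxa with their own codes. Periods are free labels on sample units, not
a hard-coded pair; every analysis accepts a period filter or pools.

## Assemblage statistics

**Rarefaction.** Sample-based, with the hypergeometric expectation
`E[S_t] = Σ_i [1 − C(T−T_i, t)/C(T, t)]`, where `T_i` is the number of
samples containing species `i`. Binomial coefficients are evaluated as
differences of `gammaln` so the curve is stable for large `T`. The
default sampling unit is the *plant taxon* (each taxon's pooled species
list is one sample), matching how such surveys rarefy; individual
sample units are available via `unit="sample"`. The permutation variant
averages species-accumulation curves over random sample orderings and
reports the across-permutation SD; it is unbiased for the analytic
curve, which the tests verify at 3 Monte-Carlo standard errors.

**Rank abundance and origin shares.** Whittaker tables rank species by
decreasing abundance with ties broken lexicographically by species code
(stable, documented). Exotic relative abundance is the summed abundance
of exotic species over the period total; the neotropical share is
computed as the complement on the percentage scale so the two raw
values sum to exactly 100. Reported percentages are rounded to one
decimal, round-half-even, with raw values always retained.

## Interaction-matrix statistics

**Host density** divides a taxon's emerged flies by its *productive*
mass only — the grams of sample units that produced at least one fly —
mirroring the "empty mass" bookkeeping of rearing surveys; an option
divides by total mass for sensitivity. Taxa with no productive mass are
omitted rather than reported as zero or infinite.

**Success rates** count a taxon as successful when its empty-mass
percentage is below 100 in any period. Empty-mass percentages are
pinned exactly to 0 and 100 at the endpoints, because floating-point
summation order could otherwise leave an all-empty taxon
epsilon-below 100 and flip its success flag.

**Spearman correlations** use midranks; ρ is the Pearson correlation of
the ranks. The two-sided p-value is an exhaustive permutation
enumeration for n ≤ 10 (exact under ties) and the
`t = ρ√((n−2)/(1−ρ²))` approximation above. A constant vector is an
error, not a NaN.

## Niche breadth (Magnacca rule)

Specialist iff (i) the top plant family holds at least two-thirds of
the species' breeding records and (ii) every other family holds at most
one quarter **of the total** — both comparisons inclusive and computed
in integer arithmetic (`3·top ≥ 2·total`, `4·other ≤ total`). The
source criterion's prose reads "<25% of the remaining records", but its
worked example (≥ 40 of 60 in one family, no other family above 15)
only holds for the total-based inclusive reading; worked examples beat
ambiguous prose, so that is the default and a `strict=True` flag
implements the literal remaining-records reading. Records are
colonized sample units by default (one record per fly × sample-unit
occurrence); emerged-individual weighting is an option, because
abundance-weighted breadth answers a different question.

## Origin-class occupancy

The binary matrix is partitioned by (fly origin × host origin);
hybrid-origin hosts belong to no block and are excluded by default
(excluding them is what makes the shipped survey table internally
consistent: 21 N + 28 E hosts × 6 N + 10 E flies = 784 possible pairs,
142 observed = 18.11%; the printed "29 taxa" header and a "15/174" cell
contradict the table's own 280-pair cell and its 8.93% = 15/168
percentage, so the corrected 28-host block sizes are used downstream
while the fixture stores the printed cells verbatim).

**Chi-square.** Each possible pair is occupied or not, so the four
cells are independent binomials, not categories of one multinomial. The
count-scale statistic is therefore the homogeneity-of-proportions form
`χ² = Σ (O_c − M_c p̄)² / (M_c p̄ (1−p̄))` with `p̄ = ΣO/ΣM`, identical
to the 2×4 contingency-table chi-square (df = 3, one proportion
estimated). Omitting the unoccupied column — i.e. summing
`(O−E)²/E` over the four occupied cells only — deflates the statistic
by the factor `(1−p̄)` and drives the type-I error of a nominal 5% test
down to ~1.5%; the calibration experiment below measures the
implemented form at ~4–5%. The percentage scale (cell percentages as
observations, overall percentage as expectation) is provided purely as
a compatibility mode for survey-style reporting. On the shipped table
it gives 7.317 at full precision and 7.311 when fed the printed
percentages as-is; the printed cell 24.28 is a truncation of
24.2857…% (round-half-even would print 24.29), so exact reproduction
of 7.311 requires the printed numbers as inputs
(`rearingnet.percentage_gof`), not re-rounding from counts. The two
scales can disagree substantially — on the shipped table the count
scale rejects (17.65, p < 0.001) while the percentage scale does not —
because the percentage scale ignores the block sizes `M_c`.

**Post hoc binomial tests.** Each cell is tested against
`p₀ = p̄` with the exact minimum-likelihood two-sided p-value
(`Σ P(X=j)` over all `j` with `P(X=j) ≤ P(X=k)`, a `1+1e−7` relative
guard absorbing floating-point ties); the central (doubled-tail)
variant is available by flag. No multiple-testing correction is applied
across the four cells, matching standard practice for this survey
design. The shipped table's printed p-values for the two
neotropical-host cells (0.067, 0.064) are not reproducible under this
natural construction (k = O_c, n = M_c, p₀ = p̄ gives 0.42 and 0.72);
the implementation keeps the natural reading and the discrepancy is
simply noted. The exotic-host cells reproduce the published
direction/significance pattern (below expectation p ≈ 0.001, above
expectation p ≈ 0.01).

## Synthetic-survey generator

The generator emulates the structure the analyses assume: per-period
surveys of uniformly host-assigned sample units with lognormal masses
(default μ = 4.8, σ = 1 on the log-gram scale, ≈ 200 g median);
dominance-skewed fly relative abundances as iid log-series draws with
parameter `x` derived from Fisher's α and the species count via
`N = α(e^{S/α} − 1)`, `x = N/(N+α)` (default α = 2 gives a top-species
share around 0.5); Bernoulli origin classes (10/16 exotic flies, 28/49
exotic hosts by default); a binary compatibility matrix drawn per
origin pair with `(p_NN, p_NE, p_EN, p_EE) = (0.15, 0.10, 0.20, 0.25)`
by default; and negative-binomial emergence counts with mean
`mass × density_per_g × rel_abundance` for compatible pairs (default
density 2 /g, dispersion 0.5 — a 600-sample survey then yields a few
tens of thousands of flies, the scale of the shipped survey).
Emergence and detection are deliberately collapsed into `density_per_g`
because the survey design observes emergences only. All randomness
flows from one integer seed through fixed named substreams
(community / compatibility / samples / counts), making datasets
byte-identical for identical (config, seed).

What the generator does **not** emulate: temporal population dynamics
between periods, climate seasonality, parasitoids or interspecific
competition, non-uniform host availability, and any correlation between
a species' abundance and its origin or compatibility. Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not realism of any particular ecological mechanism.

**Detection saturation.** Observed occupancy estimates compatibility
only when every compatible pair is detected with near-certainty; at low
density, rare log-series species have pair-detection probabilities well
below 1 and occupancy is biased low. The calibration, power and
recovery experiments therefore use `density_per_g = 25` and
`nb_dispersion = 2` with the other defaults, which the
consistency test (bias shrinking across 40 → 160 → 640 samples per
period) confirms is deep sampling for this community size. Under those
conditions the count-scale GOF rejects a true homogeneous table in
≈ 4–5% of 1000 replicates at α = 0.05, rejects the default
heterogeneous table (`p_EE − p_NE = 0.15`) in > 90% of 200 replicates,
and per-class Clopper–Pearson 95% intervals cover the true
compatibilities in ≥ 90 of 100 seeds. These replicate counts keep the
whole experiment suite around a quarter minute on one core.

## Degenerate inputs and tie-breaks

Empty assemblages, unknown period labels, zero breeding records,
constant correlation inputs, all-zero occupancy and p₀ ∈ {0,1} raise
errors naming the condition rather than returning NaN. Rank ties break
by species code; the breadth rule's top family breaks count ties
lexicographically. Edge-list exports are sorted (fly code, then taxon
code) and bit-reproducible.

## Known limitations

* Host-range degree statistics depend on registry completeness; taxa
  never sampled still count toward occupancy block sizes, as in the
  source survey design.
* The percentage-scale chi-square is reported for compatibility but has
  no sampling-theory justification; conclusions should rest on the
  count scale and the per-cell exact tests.
* The exact permutation Spearman p-value enumerates up to 10! orderings
  (~3.6 M); beyond n = 10 the t-approximation is used rather than Monte
  Carlo.
* Breadth classification at the plant-family level inherits the
  registry's family assignments; synthetic families are arbitrary
  two-taxon groupings, adequate for exercising the rule but not for
  ecological interpretation.
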