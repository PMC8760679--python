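# Methods

## The model behind the pipeline

The analysis treats a genome-scale metabolic model (GSMM) purely as a set
of reaction identifiers attributed to a taxon at species, genus, or family
rank. An ASV inherits the reaction repertoire of the models whose taxon
name equals its own lowest resolved rank: species is tried first, then
genus, then family, and the first rank with at least one match wins. This
"lowest rank with a match" rule means an ASV with a species assignment that
matches no model still maps through its genus; ASVs resolved only above
family, or matching nothing anywhere, are excluded from the reaction-level
analysis entirely. Name comparison is exact after normalization
(whitespace trimmed, underscores collapsed to spaces, case-insensitive) —
fuzzy matching would silently change results, so it is deliberately absent.
When several catalog entries share a taxon name, all of them count: the
expectation `E(i, j)` is the fraction of ASV *j*'s matched models (after
deduplication by model id) that contain reaction *i*, so each column of E
is a probability profile over reactions.

The per-sample normalized reaction abundance is the weighted mean
`a_r(i) = Σ_j a_ASV(j) E(i,j) / Σ_j a_ASV(j)` **over mapped ASVs only**.
Restricting both sums to mapped ASVs is a consequence of the formula's
structure, not a convenience: unmapped ASVs have no E column, and admitting
them to the denominator would rescale every reaction of a sample by the
same factor, breaking the invariant that `a_r(i)` lies between the smallest
and largest `E(i, ·)` entries. The same structure makes `a_r` exactly
invariant to multiplying a sample's counts by any positive constant, so raw
counts can be used without prior normalization. A sample whose mapped ASVs
have zero total count has no defined profile and is rejected with the
sample named.

## Statistical comparisons

Reactions are compared between diet pairs with a two-sided two-sample
t-test. The default is Student's pooled-variance test; an unqualified
"two-sample t-test" most commonly denotes the pooled form, and with equal
group sizes (13 vs 13 in the default design) Welch's statistic is nearly
identical — a `welch=True` flag switches to it. A reaction whose values
have zero variance in both groups is untestable (there is no within-group
error to estimate) and is excluded from the multiple-testing universe
rather than given a fabricated p-value. Benjamini–Hochberg correction runs
over the testable reactions of each pair; significance is adjusted
p ≤ 0.05. The BH step itself is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; the test
suite checks it against a literal step-up implementation.

Pathway (subsystem) enrichment uses a one-sided Fisher's exact test per
subsystem on the 2×2 table of significant / non-significant × inside /
outside, over the pair's tested reactions, BH-corrected across subsystems.
One-sided over-representation is the default because the question is which
pathways are *enriched* among significant reactions; a two-sided
alternative is exposed. Reactions annotated to several subsystems count
once in each (tables are per-subsystem, not a partition). Each enriched
subsystem is assigned a direction from the mean t-statistic of its
significant reactions: the first diet if positive, the second if negative,
and "mixed" when the signs disagree and the mean lies inside its own 95%
confidence half-width — a reporting convention, flagged as such, since a
heat-map color cannot carry a two-sided answer. The enrichment universe is
the pair's tested reactions (not the full catalog): untested hypotheses
contribute neither signal nor denominator.

PCA is computed by singular value decomposition of the column-centered
matrix (optionally z-scored first; the z-scoring path is the default for
reaction profiles, and the "standardized ASVs" path standardizes relative
abundances per ASV with a flag for raw counts). Variance-explained
percentages are fractions of total variance, hence non-increasing and
summing to 100% over all `min(n−1, p)` components; each component's sign is
fixed by forcing its largest-magnitude loading positive so orientations are
reproducible. Group mean scores carry t-based 95% confidence intervals
with group n−1 degrees of freedom, appropriate for the small per-group
sizes this design uses.

## Community summaries

Core ASVs use prevalence ≥ threshold (so exactly 80% prevalence is core at
the 80% threshold — the inclusive convention) with presence defaulting to
raw count > 0; a relative-abundance floor is available and is the rule used
for between-sample-type overlap, where an ASV is present in a group if it
reaches 0.05% relative abundance in at least one of the group's samples.
Rarefaction draws a multivariate hypergeometric subsample (without
replacement) per sample at a fixed seed; samples below the target depth are
dropped with a warning. Shannon's index uses the natural logarithm by
default (a base flag exists), Pielou's evenness is H / ln(richness) and is
defined as 0 for single-taxon samples to avoid NaN propagation, and Faith's
PD is the branch length of the minimal subtree spanning the root and all
present leaves. PD is computed by an in-package postorder branch sum
because the analysis must accept multifurcating (e.g. star) trees; the
implementation is cross-checked against scikit-bio's `faith_pd` on
bifurcating trees in the test suite.

## The synthetic-data generator

The generator emulates the shape of a multi-diet feeding trial read out by
16S sequencing. Its defaults are the study conditions: 6 dietary groups
(labelled CD, IM, DFIM, DCIM, IO, EX) × 13 digesta samples, mean depth
50,000 reads with a lognormal coefficient of variation of 0.3, 60 ASVs, a
catalog of 80 models over 150 reactions in 12 subsystems, and taxonomy
resolution fractions of 10% species / 50% genus / 25% family / 15% above
family — the last guaranteeing a known unmappable fraction that exercises
the exclusion rule.

Counts are Dirichlet–multinomial: each sample's proportions are drawn from
a Dirichlet centred on its group's mean composition with concentration 200
(moderate overdispersion of the kind amplicon data show; the parameter is
exposed), then counts are multinomial at the sample's depth. Group mean
compositions are a shared lognormal rank-abundance profile; one designated
group receives configurable multiplicative fold changes on chosen ASVs and
is renormalized, while all other groups equal the reference, so
between-unshifted-group comparisons are exactly null. Because the planted
shift is applied after the base composition is drawn and consumes no
random numbers, re-running the generator with the same seed and a
different `planted_shift` reproduces the same base community — the
intended idiom for choosing a target ASV from a pilot draw.

Catalog reaction content is structured at the (pathway, family) level:
subsystems are contiguous reaction blocks, a core fraction (60% by
default) of subsystems forms a near-ubiquitous backbone (per-family
inclusion probabilities in [0.85, 1)), and accessory subsystems have a
prevalence shared across families with sparse family-specific deviations
(probability 0.2) plus per-reaction jitter. This mirrors how pathways are
gained and lost largely as units in pan-genomes, and it is what gives
pathway enrichment something to find: if pathway membership were
independent of taxonomy, a compositional shift would scatter significant
reactions uniformly across subsystems and over-representation would be
impossible by construction.

The `GroundTruth` object carries the exact per-group mean proportions, the
true expectation matrix (computed by an exhaustive loop-based matcher kept
deliberately separate from the pipeline's vectorized path), per-group
expected reaction abundances by explicit double summation over those
means, and the set of "truly shifted" reactions — those whose expected
between-group difference reaches δ = 0.02, the threshold separating
recoverable from negligible effects. The expected abundance is the
plug-in value at the mean composition (a ratio of expectations); with the
concentrations used, the gap to the exact expectation of the ratio is far
below the tolerances at which it is consulted.

What the generator does **not** emulate: read-level errors and chimeras,
contaminant ASVs, batch effects, 16S copy-number variation, correlation
between taxon abundance and sequencing depth, and catalog mislabelling.
Passing tests therefore show that the pipeline's arithmetic, matching
rules, and error control behave as specified on overdispersed
compositional data with known structure — not that any particular real
community's functional profile is accurately predicted, which also depends
on the coverage and quality of the external model collection.

## Numerical and scale choices

Standardization uses the n−1 variance denominator and zeroes (and flags)
zero-variance columns. Ties in top-taxa ranking break lexicographically.
Degenerate inputs fail loudly with the offending identifier named:
duplicate ids, negative counts, taxonomy gaps (truncated with a warning),
trees missing leaves, empty sample subsets, zero mapped abundance. The
replicated simulation studies in the tests and the acceptance script run
at the default design with 100–200 count resamples per study (the ground
truth and expectation matrix are fixed once per study and only counts are
redrawn), and the acceptance script's enrichment demonstration uses a
larger catalog (400 reactions / 20 subsystems / 100 models) with a 3-fold
shift of a mid-abundance taxon: Fisher's test needs a few dozen reactions
per pathway to resolve over-representation, and a massive shift of a
dominant taxon makes nearly every reaction significant, leaving
over-representation undefined — the moderate, targeted setting is the
regime the enrichment question is about.

## Known limitations

Taxon-name matching inherits whatever disagreements exist between the
taxonomy used for ASV assignment and the catalog's labels; normalization
absorbs formatting drift only. The direction label of an enriched pathway
compresses a distribution of t-statistics into one of three values and
should be read alongside the per-reaction table. Reaction abundances are
predictions of genomic capacity, not measurements of expression or flux;
the usual caveats about inferring function from 16S apply.
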