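# Methods

This note documents the models and procedures roostnet implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical and design decisions a user should
know before trusting the output on their own data.

## Data model

The atomic observation is a capture record: one ringed individual, one
roost, one calendar date. Boxes are never checked twice in a day and the
field protocol revisits a roost at most once per 14 days, so a capture
occasion is a (roost, date) pair and no finer timestamp is modelled. A
*colony* is the set of individuals sharing one (roost, date); colonies
are ephemeral — the same bats in the same box a week later are a new
colony. Sex and species must be constant per ring number (a violation
aborts loading); verbatim duplicate rows are dropped with a warning,
since transcription duplicates are an expected field artefact rather
than an error. Roost coordinates are planar metres in any projected CRS;
at a woodland-sized site (a few km across) geodesic corrections are far
below the positional error of a box location, so none are applied.

## Association network

Two individuals are associated iff they share at least one colony. Edges
are binary and unweighted: with per-individual capture counts mostly in
the single digits, repeat co-occurrence counts are too sparse to support
a weighted index, and the downstream methods (betweenness decomposition,
join counts) are defined on the unweighted graph. Co-occurrence counts
are retained as an `n_shared` edge attribute for diagnostics only.
Weighted association indices (half-weight, simple ratio) are
deliberately out of scope.

Before structural analysis the network is filtered: individuals captured
once are removed (a single capture carries no information about
association stability), then individuals with no remaining associations.
The two filters commute; the order is fixed only for reproducible
bookkeeping. All seasons are pooled into one network by default — the
per-season data are too sparse to analyse separately, and pooling makes
*absence* of association across five years strong evidence of social
separation. Exclusion counts are logged and conserved in the pipeline
report (individuals in = analysed + excluded-once + excluded-isolated).

## Social groups: Girvan–Newman with modularity selection

Edge betweenness is the number of shortest paths between all node pairs
passing through an edge, with tied shortest paths sharing one unit of
contribution equally (fractional counting — the convention of the
algorithm's source literature; computed via networkx, cross-checked in
the tests against explicit path enumeration). The decomposition removes
the current highest-betweenness edge and **recomputes betweenness after
every removal**; one-shot removal is cheaper but is not the cited
algorithm. Each time the component count increases, the modularity

    Q = Σ_i (e_ii − a_i²)

is evaluated for the component partition **on the original edge set**
(e_ii = fraction of edges within group i, a_i = fraction of edge ends in
group i). The partition maximising Q is returned, with the full
(n_components, Q) trace retained so users can apply their own convention
for, e.g., whether singleton components count as groups. Q of the
one-group partition is exactly 0, and Q can be negative for bad
partitions; "ranges from 0 to 1" describes the selected optimum, not a
clamp. Q > 0.3 is the conventional structure threshold.

Determinism: among edges tied on maximal betweenness, the
lexicographically smallest (sorted endpoints) is removed; among
partitions tied on Q, the coarsest (first encountered) wins — strict
`>` comparison implements both rules at once, since successive
partitions only get finer. Networks that start disconnected are handled
by seeding the initial partition with the input components; initial
components are never merged. No alternative community methods (Louvain,
spectral) are provided: the point is this algorithm, done exactly.

## Sex structure

The null model for both tests permutes sex labels over nodes with the
edge structure fixed: under the null, network position is unrelated to
sex, while the degree sequence and label counts are preserved. Edge
rewiring is *not* used — it answers a different question. Join counts
(MM, FF, MF) partition the edge set in the observed data and in every
permutation; both tails are always reported per category, since
assortment can show as an excess of same-sex edges, a deficit of
intersex edges, or both. The degree comparison uses a pooled two-sample
t statistic (females minus males) referred to its permutation
distribution, one-tailed by default for the directional hypothesis that
females are more central. p-values use the add-one estimator
(1 + #extreme)/(n_perm + 1), which cannot return 0 and is valid at any
permutation count; the default is 10,000 permutations. A zero-variance
degenerate t (all degrees equal) is defined as 0 so that complete graphs
give p ≈ 1 rather than an error.

## Lagged association rates

g(τ) estimates the probability that, given individuals a and b were
associated at occasion t₁, they are associated again at an occasion t₂ =
t₁ + τ at which a was captured. Events are counted over *ordered*
(focal, associate) pairs so that the four directed sex classes (M–M,
F–F, M–F, F–M) are distinct: the denominator counts (a, b, t₁, t₂) with
a-b associated at t₁ and a captured at t₂; the numerator additionally
requires association at t₂. Conditioning on the focal's capture at t₂
means individuals stop contributing after their last observation, so
emigration and mortality do not bias the curve. A consequence worth
knowing: the estimator is **not calendar-symmetric** — reversing time
swaps which end of an event must show association and which must merely
show capture, so g computed on a reversed calendar can differ. This is
inherent to the estimator's definition, not an implementation artefact.

Default lag bins are [1,10), [10,30), [30,100), [100,200), [200,300),
[300,400), [400,500), [500,∞) days: fine resolution at short lags where
roost-switching dynamics live, with breaks at the ~100-day
casual-acquaintance scale and the 400–500-day between-season scale.
Bins are fully configurable. A bin with an empty denominator is reported
as missing, never as 0.

The null association rate recomputes g after shuffling, within each
occasion, the roost assignments of associate-class individuals captured
that day. This preserves every individual's capture schedule and every
colony's class composition while randomising who roosts with whom; it is
assumption-transparent in a way closed-form nulls are not. The default
is 20 permutations (the null is an average, not a tail estimate, so few
permutations suffice); it is seeded and configurable. Note the null's
power depends on the sampling design: if only one colony is observed per
occasion there is nothing to shuffle across, and the null collapses onto
the observed curve.

Standard errors come from a leave-one-block-out jackknife over
consecutive 30-calendar-day blocks anchored at the first capture date (a
short final block is kept as-is): SE² = ((n−1)/n) Σ(gᵢ − ḡ)² over the n
replicates in which the bin is populated; replicates with an empty bin
are excluded from that bin with the count reported. Block jackknife SEs
of association rates are known to understate sampling error; outputs
carry that caveat in metadata rather than any ad-hoc inflation.

## Roost home ranges

A group's range is the 100% minimum convex polygon (convex hull — no
percentage coring) of its supporting roosts. Filters, in order: a roost
supports a group only if at least two group members were recorded in it
on one date ("used by single bats" is interpreted per group: a roost
whose colonies never contained more than one member of that group);
kept roosts more than 1 km from every other kept roost of the group are
dropped (checked once against the post-first-filter set, not
iteratively — the simplest reading of an isolation rule); groups left
with three or fewer roosts are excluded, since a hull on ≤ 3 points is
not a credible area estimate. Areas are km² from planar hull geometry
(shapely), optionally intersected with a polygonal habitat mask
(cropping never increases area). Raster habitat data and kernel-density
range estimators are out of scope.

Overlap conventions are explicit because the denominator is a genuine
choice: intra-species overlap is union-normalised (area covered by ≥ 2
of the species' ranges over area covered by ≥ 1); inter-species sharing
is reported both union-normalised and per species. The maximum number of
ranges covering any point is computed by exact incremental polygon
overlay. Radio-fix fidelity classifies each fix as inside the polygon or
not and, for outside fixes, buckets the Euclidean distance to the
polygon at 15 m and 100 m.

The area regression is OLS of range area on group size, species
(dummy-coded), and sampling effort (mean recaptures per individual in
the group), with a marginal F test per term — full model against the
model without that term. Rank deficiency raises an error naming the
collinear term. No multiple-testing correction is applied (three
planned terms, one model).

The roost-sharing test builds the 2×2 table of roost usage (used/not
used by each species) from user-supplied counts and applies Pearson's
chi-square with 1 df, no continuity correction, with a warning when an
expected cell falls below 1. What counts as an "available" roost (all
boxes vs ever-used boxes) materially changes the answer and is left to
the caller.

## Synthetic populations

The generator emulates the *sampling design and statistical structure*
of a multi-season box-check ringing study, nothing more. Planted
structure: social groups with fixed membership and sex composition
(default: mixed female-core groups of both species at 60–90% female,
plus > 90%-male Daubenton's bachelor groups; sizes 8–14, inside the
2–35 range real colonies span); each group owns a spatial cluster of
roosts (uniform in a 150 m disc) on a 600 m grid, so clusters — and
hence true MCPs — are disjoint by default, with the grid spacing as the
overlap knob. Dynamics per occasion (every 14 days, May 1–Oct 15, 5
seasons): each group occupies one roost of its cluster, never reusing a
roost within 14 days; with mixing probability m (default 0.01) an
individual instead spends the day with a randomly chosen other group of
the same species — a temporary visit, the only source of inter-group
edges, matching the observed rarity and casualness of inter-group links
(group merges are deliberately not modelled). Observation: each colony
is checked with survey probability 0.1 (only a fraction of boxes is
checked on any day), and each present individual is detected with
probability 0.7. These defaults give ≈ 4 captures per individual over
five seasons and inter-group edge fractions of a few percent — the scale
of the real frequency tables — while keeping within-group networks
dense enough for recovery. Cross-species roost sharing is never
simultaneous. Juvenile mid-season recruitment exists but defaults off,
as the analyses pool age classes.

Radio-track simulation draws daily day-roost positions from the
individual's group cluster, with optional excursions displaced a fixed
distance beyond a hull vertex (guaranteeing outside-but-near fixes with
a known distance bound).

What the generator does **not** emulate: energetics, demography,
movement mechanics, roost-quality preference, the real study's spatial
sampling bias (a uniform schedule is the default and no field numbers
exist to calibrate a biased one), band loss or misreads. Passing tests
on synthetic data therefore demonstrate the *algorithms* are correct and
the chain recovers planted statistical structure at realistic sparsity —
not that any biological conclusion transfers to a particular real
dataset.

All stochastic operations take an explicit seed (numpy Generator); there
is no hidden global RNG state, and a fixed seed reproduces output
byte-for-byte, including the pipeline's JSON report.

## Numerical choices and degenerate inputs

* Modularity is undefined (error) on an edgeless network; inter-group
  fraction likewise.
* MCPs require ≥ 3 non-collinear points; anything less raises a
  degenerate-geometry error rather than returning a zero-area sliver.
* Hull areas are exact to shapely's double precision; rigid-motion
  invariance holds to ~1e-9 relative except for near-collinear point
  sets whose hulls are themselves numerically fragile.
* Empty LAR bins and strata with no recaptured individuals report
  missing values (NaN), never 0.
* Betweenness ties are broken lexicographically; all reported p-values
  are add-one estimates in (0, 1].
* The chi-square test validates count consistency (shared ≤ each
  species' total ≤ grand total) before computing.

## Problem sizes used in validation

The bundled validation suite runs at desk scale, chosen so each check
isolates one property: exhaustive oracles on 3–8 node/individual
fixtures (where full enumeration is feasible), 500 null simulations at
300 permutations each for test calibration (the add-one p-value is valid
at any permutation count), and 20 simulated populations of five groups
(8–15 individuals each) for end-to-end recovery. The defaults users get
(10,000 permutations for assortment tests) are the conventional
reporting standard, not what the validation suite runs.

## Known limitations

* Girvan–Newman recomputes betweenness after every removal: O(E²·V)
  in the worst case. Fine for networks of hundreds of nodes (the
  intended scale); for thousands, expect minutes to hours.
* The within-occasion permutation null is weak when occasions rarely
  contain multiple colonies (see above).
* Jackknife SEs are optimistic; treat them as lower bounds.
* The pipeline's range "effort" covariate uses captures − 1 per
  individual averaged over the group, which differs from other effort
  definitions (e.g. box checks per area); supply your own regression
  inputs if you need a different one.
* Identifiers are trusted: no modelling of ring loss or re-use.
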