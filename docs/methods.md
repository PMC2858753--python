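# Methods

## Graph construction

A reaction table carries, per reaction: EC numbers, educts, products,
curated *main pairs* (the educt–product pairs between which carbon atoms
are transferred), a spontaneous flag and pathway maps. Only main pairs
become edges; transfers of phosphate groups, electrons etc. never do.
The builder does not infer atom mappings — carbon transfer is taken from
the curation in the input, which is how such tables are produced in
practice.

Currency metabolites (default set: ATP, ADP, AMP, NAD⁺, NADH, NADP⁺,
NADPH, CoA, H₂O, CO₂, Pi, PPi, H⁺, O₂, NH₃; configurable, since any
given universe may use different identifiers) are excluded as nodes.
Without this exclusion ATP and NADH would be hubs of enormous degree and
every path-based statistic would be physiologically meaningless.

An organism's graph selects the reactions whose EC set intersects the
organism's enzyme complement; spontaneous reactions (empty EC set) are
added to every graph by default. Parallel contributions collapse to one
edge annotated with all supporting reaction ids; orientation is parsed
but all analysis is on the simple undirected graph. Isolated edges
(two-node components) are *retained* in the graphs and counted by the
`isolated_edges` statistic; `trim_isolated_edges` exists as an explicit,
optional step rather than being baked into construction, so both the
pre- and post-trim views are available.

## Statistics panel conventions

The organism graphs are fragmented, so conventions for disconnected
graphs must be explicit:

* **diameter** — maximum *finite* shortest-path length (never infinite);
* **mean path length** — sum of finite shortest-path lengths over
  unordered pairs divided by `N(N−1)/2`: disconnected pairs contribute
  zero to the numerator but stay in the denominator. This makes the
  statistic fall as a graph fragments, which is the behaviour the
  random-shrinkage contrast needs. (The alternative — averaging over
  connected pairs only — would *rise* on fragmentation and is not used.)
* **global clustering** — transitivity, `3·triangles / connected
  triples`; mean local clustering is available via the
  `clustering="average"` option but is not the default.
* **degree-tail fit** — least squares on `(log₁₀ k, log₁₀ count)` for
  `k ≥ k_min`, default `k_min = 2`. Dead-ended metabolites (degree 1)
  dominate curated core-metabolism graphs and sit far off the power-law
  line; the exclusion applies to tail fitting only, never to any other
  statistic.

## Statistical tests

* Exact Mann-Whitney enumerates all `C(n₁+n₂, n₁)` group assignments
  over the pooled midranks (tie-aware) for combined n ≤ 20; two-tailed p
  uses the symmetry of U about `n₁n₂/2`. The null distribution is cached
  per (group size, midrank multiset), so simulation studies pay the
  enumeration once. The approximate mode is the normal approximation
  with tie correction. Note the smallest attainable exact p for 8 vs 8
  is `2/12870 ≈ 1.6·10⁻⁴`; approximate p-values below that for such
  samples are artifacts of the approximation.
* Kruskal-Wallis (tie-corrected H) with Dunn's pairwise z tests;
  pairwise p-values are Bonferroni-multiplied over all pairs. Bonferroni
  is the conservative default; the adjustment family is a choice, not a
  canon.
* Spearman's ρ is the Pearson correlation of average ranks; p is by
  exact permutation (all n! orderings) for n ≤ 9, t-approximation
  otherwise.
* Fisher's exact 2×2 two-tailed p sums the hypergeometric probabilities
  of all tables (fixed margins) no more probable than the observed one —
  the most common two-sided convention.

## Cofactor classification

“ATP-consuming” means ATP appears among the *educts* (consumption is
directional); “NAD(P)H-utilizing” means NADH or NADPH appears on
*either* side (redox cofactors cycle). Both side rules are configurable
(`atp_side`, `nad_side` ∈ {educts, products, both}) because neither
convention is universal. Classification is evaluated on the full
reaction equation, *before* currency filtering: the cofactors are
excluded as graph nodes but still counted here. Percentages are taken
over the organism's reaction count, and network size for the correlation
is that same reaction count.

## Random-shrinkage null model

“Shrinking to a given size” removes *graph edges* uniformly at random,
without replacement, until a target edge count is reached; nodes left
with degree 0 are dropped, isolated edges are retained and counted.
Edge count is the targeted quantity (node loss is passive) — in ensemble
summaries the edge count is pinned exactly while node counts fluctuate.
An alternative would be to remove whole reactions (potentially several
edges at once); with one or two main pairs per reaction the two differ
little, and edge removal matches how the ensemble is summarized.
Replicate r of an ensemble draws from the child stream
`SeedSequence([seed, r])`, so ensembles are bit-reproducible and can be
extended without disturbing earlier replicates.

## Synthetic-data model

The generator emulates the *statistical* shape of a curated
core-metabolism universe — it makes no attempt at real chemistry,
compartments or genome sizes.

**Reference universe.** Reactions are created sequentially
(`n_reactions = 1200` by default); each picks one main pair (two with
probability 0.10). A pair normally anchors on an existing compound and
adds a new one with probability 0.65; with probability 0.015 both
endpoints are new, seeding an isolated edge. Anchors are drawn from a
three-way mixture:

| mechanism | prob. | role |
|---|---|---|
| degree-proportional attachment, weight `deg^1 + 0.5`, saturating at degree 50 | 0.45 | heavy-tailed hubs (pyruvate-like central metabolites) |
| uniform over current dead ends (degree ≤ 1) | 0.40 | long pathway chains |
| uniform over all compounds | 0.15 | branching |

The saturation and chain terms matter: pure preferential attachment
yields a single huge hub (degree > 100) and a compact graph whose
diameter *rises* under random edge deletion — the opposite of how
curated metabolic networks behave. With the mixture, the reference graph
lands near 900 metabolites / 1200–1350 edges with maximum degree ≈ 20,
diameter 15–22, and a degree tail that is log-log linear (r² ≈ 0.90–0.98
across seeds) with slope ≈ −2.9 — the shape of real curated networks.
Each reaction receives ATP (educt side, with ADP produced) with
probability 0.18 and NADH or NADPH (random side) with probability 0.22;
2% of reactions are spontaneous; every enzymatic reaction carries one
unique synthetic EC number.

**Organism cohorts.** Each enzymatic reaction is retained independently
with probability `clip(retention · (1 + atp_bias · uses_atp), 0, 1)`.
The default cohort has 8 obligate-parasite-like organisms (retention
0.10–0.26, ATP bias graded 1.2 down to 0.5 — the retention advantage of
ATP-consuming reactions compounds as loss pressure grows, which produces
the smooth %ATP-vs-size gradient seen in real panels instead of a
two-block step) and 8 free-living/facultative-like organisms (retention
0.35–0.48, no bias). Cohort mean edge counts land near 290 and 560.
Organism j of a study uses seed stream `[seed, 1000 + j]`.

**What the generator does *not* emulate.** Gene loss is independent per
reaction, so synthetic parasite-like graphs fragment the pathway chains:
their diameters are *smaller* than the non-parasite cohort's and their
isolated-edge counts resemble the random-deletion ensemble. Real
reductive evolution removes whole pathway blocks and keeps the remaining
network coherent (diameters comparable across groups). Passing the
pipeline's tests on synthetic data therefore demonstrates that the
*machinery* (reconstruction, statistics, null model, correlation)
behaves correctly — not that the biological diameter-preservation
contrast is reproduced; that contrast can only be checked against the
curated organism networks, which are not redistributable with this
package (convert them with `scripts/convert_supplement.py`).

**Shrunk-tail slope.** Under 4–5× random edge thinning the *fitted*
tail slope steepens by roughly 1–2 even though the distribution stays
log-log linear. This is a deterministic property of binomially thinning
a degree distribution truncated near degree 20–50, not a property of the
implementation: thinned counts at degree j are fed by source degrees
near j/q, and for j beyond q·k_max that supply collapses faster than any
power law. Slope *stability* under thinning would require a clean power
law out to degree ≳ 100, which a ~900-node graph cannot exhibit in raw
degree bins. The robustness claim is therefore tested as linearity
(pooled shrunk-tail r² stays ≥ 0.9) plus a negative slope, not as slope
equality.

## Numerical and degenerate-input choices

* Density is reported as missing (`None`) for graphs with < 2 nodes;
  empty selections build empty graphs with a warning rather than
  erroring.
* All-tied samples: Mann-Whitney returns p = 1 with a warning; a
  constant vector makes Spearman's ρ undefined (NaN, flagged); a zero
  margin makes Fisher's p = 1 with a warning.
* Tail fits require ≥ 3 distinct supported degrees ≥ k_min.
* Every stochastic step takes an explicit seed; replicate and organism
  streams derive from the root seed via documented `SeedSequence`
  splitting. Fixed inputs give bit-identical outputs.

## Problem sizes used by the test and acceptance runs

The default synthetic scale (1200 reactions, 16 organisms, 10 shrinkage
replicates) is used throughout; the ground-truth-recovery simulations
use 100 replicate studies per condition, and the brute-force oracle
comparisons use 100 random graphs of up to 60 nodes, where exhaustive
BFS and triple enumeration are exact and fast.
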