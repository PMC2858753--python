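# coremetnet

Comparative analysis of **core metabolic networks** — the pathway set
(glycolysis, gluconeogenesis, Krebs cycle, pentose phosphate, purine /
pyrimidine and amino acid metabolism) presumed ancestral to parasitic and
free-living eukaryotes alike — aimed at the question: *how do metabolic
networks shrink during the reductive evolution of obligate endoparasites,
and which properties does selection preserve?*

The package is a library with a thin `coremetnet` command-line wrapper,
written for systems biologists who want to:

* reconstruct metabolite graphs from KEGG-style reaction tables under
  carbon-transfer rules: a reaction's curated main (educt, product) pairs
  become undirected edges; currency metabolites (ATP, NADH, H₂O, …) are
  excluded as nodes so they cannot become artifactual hubs; spontaneous
  non-enzymatic reactions supplement every organism's graph;
* compute the standard whole-graph statistics panel — N, E, density
  `2E/N(N−1)`, mean/max degree, diameter (longest *finite* shortest
  path), mean path length (finite pairs over `N(N−1)/2`), transitivity
  `3·triangles/triples`, and the count of isolated edges (two-node
  components) — plus degree distributions and log-log tail fits
  (degree-1 nodes excluded, `k ≥ 2`);
* contrast natural network reduction with a **random-shrinkage null
  model**: deleting edges uniformly at random until parasite size is
  reached fragments the graph (collapsing diameter, accumulating
  isolated edges) while leaving the scale-free degree tail intact;
* quantify **cofactor retention**: the share of ATP-consuming reactions
  (ATP among the educts) rises as core networks shrink — Spearman's ρ of
  %ATP vs reaction count is strongly negative — while NAD(P)H-utilizing
  reactions are lost preferentially;
* run the statistics the analysis needs with exact small-sample
  behaviour: tie-aware exact Mann-Whitney (full enumeration for combined
  n ≤ 20), Kruskal-Wallis with Dunn's Bonferroni-adjusted pairwise
  comparisons, Spearman with exact permutation p for n ≤ 9, and
  two-tailed Fisher's exact test;
* generate **synthetic study cohorts** with known ground truth — a
  KEGG-like reaction universe with a heavy-tailed degree distribution,
  plus parasite-like organisms derived by probabilistic enzyme loss with
  a tunable ATP-retention bias — so the entire pipeline is testable
  without any database access.

## Worked example

```bash
python examples/04_full_study.py
```

```text
reference graph: 885 nodes / 1331 edges, diameter 18
n_nodes: parasites 420.2 vs non-parasites 652.6 (Mann-Whitney p = 0.0001554)
n_edges: parasites 294.0 vs non-parasites 564.8 (Mann-Whitney p = 0.0001554)
density: parasites 0.0034 vs non-parasites 0.0027 (Mann-Whitney p = 0.0001554)
diameter: parasites 12.8 vs non-parasites 25.8 (Mann-Whitney p = 0.001088)
random shrinkage to 294 edges: diameter 12.0, isolated edges 83.2
rho(%ATP vs size) = -0.871 (p = 1.15e-05); rho(%NAD) = +0.474
outputs in scratch/full_study/
```

Reading this: the 8 parasite-like organisms have far fewer metabolites
and edges than the 8 free-living-like ones (the exact two-tailed
Mann-Whitney p = 2/12870 ≈ 1.6·10⁻⁴ is the smallest attainable for 8 vs
8), yet their *density* is higher — small metabolic networks are
relatively denser. Networks shrunk at random to the parasites' edge
count fragment (diameter 12, ~83 isolated edges vs 0 in the source),
and the ATP-consuming share of reactions rises steeply as networks
shrink (ρ = −0.87). The other examples (`examples/01…03`) demonstrate
each capability in isolation; the `coremetnet` CLI (`simulate`,
`build-graph`, `metrics`, `shrink`, `cofactors`, `correlate`,
`group-test`, `run`) exposes the same operations on files.

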