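# Methods

## Problem setting

Given condition-labelled gene lists (e.g. normal hearing NH, acoustic
stimulation AS, tinnitus Tin) and a weighted protein–protein interaction
(PPI) edge table with STRING-style integer combined scores (CS, 0–1000),
the pipeline identifies *key proteins*: the top-k high-degree proteins
(HDPs) of each condition's induced network together with their high-score
interaction proteins (HSIPs), the neighbors whose connecting edge's CS
strictly exceeds the network-wide 90th-percentile score. Key-protein sets
are then compared across conditions by exclusive Venn regions, tested for
term overrepresentation against a local annotation collection, and probed
around user-chosen focal proteins.

## Network construction and topology criteria

A condition network is the subgraph of the edge table induced on the
condition's (normalized) gene symbols, with proteins left unconnected
dropped. Seven criteria summarize each network:

| criterion | definition |
|---|---|
| nodes, edges | counts N, E |
| mean neighbors | 2E/N |
| characteristic path length | mean unweighted shortest-path length over connected unordered pairs; disconnected pairs are excluded rather than set to infinity |
| clustering coefficient | mean local clustering over **all** nodes; nodes of degree < 2 contribute 0 |
| heterogeneity | coefficient of variation of the degree distribution (population sd / mean) |
| centralization | Freeman degree centralization, Σ(k_max − k_i) / ((N−1)(N−2)) |

Degrees are unweighted edge counts; combined scores never enter the
topology metrics. Single-node graphs report an undefined (NaN) path
length with a warning. These conventions are fixed here because the
common network-analyzer tools do not document their averaging choices;
the all-node clustering average and excluded disconnected pairs are the
variants consistent with finite published values.

## Degree-preserving permutation null

Empirical significance of a topology statistic uses the Maslov–Sneppen
double-edge swap null: ⌈10·E⌉ attempted swaps per draw, rejecting any
proposal creating a self-loop or duplicate edge, which leaves the degree
sequence exactly invariant. Combined scores travel with their original
edge slot (the null statistics never read them). With n null draws
(default 1000; minimum 19) the two-sided p-value uses the add-one rule

    p = (1 + #{ |t_null − mean(t_null)| ≥ |t_obs − mean(t_null)| }) / (1 + n)

so p is bounded in [1/(n+1), 1] and never zero. Between-network
comparisons use node-level value distributions (per-node mean shortest
path distance, or per-node local clustering), summarized by Cohen's d
with pooled (n−1-weighted) sd and an unequal-variance t-test p. The swap
protocol, permutation count, sidedness and the node-level sampling are
this package's documented defaults — the procedure they implement is
standard, but no published description fixes them uniquely.

## Quantile classes and the degree–score association

For either degrees or edge scores, five classes are cut at the
20/40/60/80/100th linear-interpolation percentiles; class 0.2 holds the
top 20 % of values, and a value equal to a cut point falls to the
lower-valued class (an arbitrary but fixed tie rule). The degree–score
association is measured at class level: for each degree class the point
(mean degree of its nodes, mean CS over edges incident to those nodes) is
formed, points are pooled across the supplied networks (5 classes × 3
networks = 15 pairs for the three study conditions), and Pearson r with a
two-sided t-test (df = pairs − 2) is reported. Pairing a degree class
with its incident-edge scores — rather than co-sorting the two
independent class tables — is what makes the statistic informative: the
co-sorted version is structurally positive for any score model because
both mean sequences ascend by construction.

## Key-protein selection

HDPs: nodes sorted by degree descending; ties break by larger summed
incident CS, then lexicographic symbol order (deterministic, logged).
Default k = 3. The HSIP threshold is the network-wide 90th-percentile CS
(linear interpolation, rounded to nearest integer); partners qualify by
*strict* inequality. A partner under several hubs counts once in the
unique-member set. The packaged reference table of published key proteins
is loaded verbatim; its container deliberately does not re-check scores
against the threshold, because published tables may carry boundary-equal
scores that the strict rule would reject.

## Overlaps, enrichment, focal subnetworks

Venn regions are exclusive and partition the union (2–3 sets). Term
enrichment is a one-sided Fisher's exact test (upper hypergeometric tail)
per term, with the background fixed to the annotation collection's union
of annotated symbols and the query restricted to it; Benjamini–Hochberg
adjustment is applied within each category (CC, BP). Default reporting
keeps rows with raw p < 0.01 **and** q < 0.05 (both thresholds apply
jointly; each is independently configurable) and prints the top 5 per
category. Focal subnetworks collect the partners of user-chosen focal
proteins over a strict CS threshold taken from the **whole** network's
score distribution (median or an arbitrary percentile), then induce the
subgraph on focal ∪ partners keeping all internal edges — only
membership is score-gated, since inter-partner connectivity is part of
what the extraction is meant to display.

## Synthetic data generator

The generator emulates three features of the study data and nothing more:

1. **Scale-free-like networks at exact sizes.** Degrees are sampled from
   a truncated power law (exponent 2.2), rescaled to the target mean,
   wired by configuration-model stub pairing with self-loop/multi-edge
   rejection, and trimmed/topped-up (degree-weighted) to hit the exact
   (N, E) targets — presets 26/78, 71/751, 90/1049. A triadic-closure
   annealing pass (10·E degree-preserving swaps accepted only when they
   increase triangles) then raises local clustering above the
   configuration-model baseline. This step is essential for realism: a
   pure configuration-model draw *is* the permutation null, so its
   clustering could never test significant; empirical PPI networks carry
   excess clustering beyond their degree sequence, and the annealed
   graphs reproduce that (p ≤ 0.001 against the null at the 90/1049
   size). Setting `triadic_closure_factor=0` recovers the plain
   configuration model.
2. **Degree-coupled edge scores.** Score = floor + span·(c·rank +
   (1−c)·u) + ε, with rank the percentile rank of the edge's
   endpoint-degree sum, u uniform, ε Gaussian (sd 60), clipped to
   [150, 999] and rounded. The two parameters (coupling c, noise sd) are
   a declared family, not a claim about real combined scores. The
   packaged calibration routine grid-searches c against the target
   class-level correlation r = 0.59 at the three preset sizes; the run
   fixing the default picked c = 0.35 (mean pooled r ≈ 0.6 over 20
   seeds). Single-seed pooled r has sd ≈ 0.15 (only 15 class points), so
   recovery statements are about the mean over 20 seeds.
3. **Gene lists with an exact Venn design and planted annotations.** The
   default three-list design realizes sizes 34/77/93, union 134, an
   AS∩Tin exclusive region of 32, and a triple intersection pinned to
   the ten symbols shared by all three study lists. The exclusive NH∩AS
   and NH∩Tin regions are not individually published; the design fixes
   them at 11 and 7, one of the splits summing to 18 that satisfies
   every published constraint. All non-pinned symbols are synthetic
   (`SYN####`). Planted annotation terms contain a stated fraction of
   the query (null rate = term size / background size), so power and
   type-I behavior of the enrichment stage are directly testable.

What the generator does **not** emulate: GeneCards relevance-score
distributions, GO DAG structure, the identity of real interaction
partners, or STRING's evidence-channel score composition. Tests passing
on synthetic data therefore validate the *procedures* (selection rules,
null construction, counting, thresholds), not biological conclusions
about any real network.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data
at the study's own network sizes (26/78, 71/751, 90/1049). Permutation
nulls use n = 999 draws where a p ≤ 0.001 statement is made and n in the
19–49 range for bound/determinism checks; calibration averages 12 seeds
per grid point over a 0.05-step grid; enrichment recovery uses 50–100
seeded repetitions. Percentiles use numpy's linear interpolation;
threshold rounding is to nearest integer (banker's rounding at .5);
permutation p-values use the add-one rule; all randomness flows from
explicit integer seeds through `numpy.random.default_rng`, and every
generator is bit-reproducible given its seed.

## Known limitations

- Published headline statistics that depend on the proprietary
  GeneCards/STRING/DAVID downloads (degree values of named proteins,
  per-network thresholds, enrichment term lists) are represented as
  packaged reference data, not recomputed.
- The alias table maps only the symbol variants appearing in the
  reference data (case normalization plus PSEN→PSEN1); no general
  identifier cross-referencing is attempted.
- The permutation null assumes the observed graph admits swaps; rigid
  graphs (e.g. a triangle) return a degenerate null with p = 1 and a
  warning rather than an error.
- Characteristic path length on disconnected graphs silently averages
  over reachable pairs only; callers comparing networks of very
  different connectivity should inspect component structure first.
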