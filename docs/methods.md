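# Methods

## Scope and data model

The package analyses three linked objects: an activity table of
(assay, compound) active pairs with per-assay metadata; an undirected
simple PPI network over gene symbols; and four named marker sets mapped
onto that network (essential genes — genes whose mouse-ortholog knockout
is lethal; approved drug targets; disease genes; bioassay targets — the
proteins that target-based screens were run against).  All file formats
are plain TSV (or one-symbol-per-line marker lists) and networks export
to GraphML with typed attributes so they load directly into Cytoscape.

## Bipartite network and projection

The bipartite graph has one node per assay with at least one active
compound and one per active compound; assays with no actives are kept in
the metadata but not in the graph, so the sparsity means (pairs/assays,
pairs/compounds) are averages over *active* entities.  The degree-window
subnetwork filter measures degrees **once, on the input network**, keeps
nodes inside the inclusive windows, then drops edges with a removed
endpoint and any node left isolated.  An `iterate=True` variant
re-applies the filter to a fixed point; the one-pass reading is the
default because the window semantics ("limiting the degrees … in the
range") do not imply iteration.

The projection connects assays with Jaccard coefficient ≥ the threshold
(default 0.10, boundary inclusive).  Pairs are enumerated through an
inverted compound→assays index, so only assay pairs sharing at least one
compound are scored; the unit tests assert exact agreement with the
brute-force all-pairs computation.  The comparison uses a 1e-12 absolute
epsilon so a ratio that is exactly the threshold in rational arithmetic
is never excluded by floating-point representation.  Isolated assays are
retained by default (node counts then reflect the full assay population);
`drop_isolates=True` gives the connected view.

## Topology diagnostics

Degree distributions are normalised over all nodes (isolates contribute
at k = 0 but are excluded from log-log fitting).  The power-law fit is
ordinary least squares of log₁₀P(k) on log₁₀k — the r/R² reporting
convention of network-analysis toolboxes, not a maximum-likelihood
tail fit — and, when `outlier_sigma` is set, one round of refitting after
removing points with |standardised residual| above the cutoff
(residual SD uses n−2 degrees of freedom).  For a straight-line fit with
intercept R² equals r², and both are reported from their definitions.

Clustering uses C_i = 2n/[k_i(k_i−1)]; nodes of degree ≤ 1 get C_i = 0 by
convention and are excluded from the by-degree means (0/0 otherwise).
The overall SD is the population SD.  The hierarchy diagnostic fits the
log-log slope of the by-degree means: ≈ −1 indicates a hierarchical
C(k) ∝ 1/k profile, ≈ 0 a degree-independent (non-hierarchical) one.
Diameter is computed on the largest connected component when the graph is
disconnected.

## Neighbourhood enrichment

For a seed protein, the shell profile at distance d ≥ 1 is the fraction
of proteins at exactly that shortest-path distance that belong to the
marker set; the seed itself is excluded.  Enrichment averages these
profiles over a seed set and over `n_random` uniform draws (with
replacement) of control proteins; seeds with no protein at a given
distance are skipped at that distance rather than counted as zero, which
would deflate the mean for peripheral seeds.  The per-distance p-value is
a two-sided Wilcoxon rank-sum test between the per-seed and
per-control-trial fraction samples.  The original analysis reported
per-distance significance without naming the per-distance test; since the
rank-sum test is the only test named anywhere in that analysis, using it
on the two fraction samples is a reconstruction, and is documented as
such.

The rank-sum implementation enumerates the exact null distribution of
the rank sum when the pooled sample has ≤ 10 observations without ties,
and otherwise uses the normal approximation with tie correction and a
0.5 continuity correction (the convention of the common numerical
packages' `ranksum`).  It is tested against independent enumeration over
all 4+4 partitions of 8 distinct values and against scipy's exact and
asymptotic Mann-Whitney implementations, which are never used as the
implementation itself.

A `DistanceProfiler` caches per-node BFS distance arrays (the only
expensive part), so replicated analyses on one network — the calibration
simulations in particular — reuse distances across marker draws.
Agreement between the cached vectorised path and the plain per-seed BFS
profile is asserted in the tests.

## Characteristic distance and prioritisation

With f_i the fraction of a charged marker set at distance d_i from a
candidate, the field is E = Σ f_i/d_i² and the characteristic distance
d̂ = E^(−1/2) (+∞ when nothing is reachable).  **This formula is a
reconstruction**: the source presentation of the formula is not
available verbatim, and d̂ = (Σ f_i/d_i²)^(−1/2) is adopted because it
(a) realises the stated unit-charge inverse-square field analogy,
(b) satisfies the single-shell identity d̂ = k when all charge sits at
distance k, (c) can fall below 1.0 only under strong first-shell
concentration, matching the stated behaviour for essential candidates,
and (d) produces values in the published ranges (≈1.3–1.9 to essential
genes, ≈3.0–5.9 to drug targets).  The candidate itself is excluded from
both numerator and denominator of its own profile; unreachable charged
members stay in the denominator (they weaken the field), with a
reachable-only variant available by renormalising the profile.

Prioritisation drops candidates that are already drug targets and
candidates with PPI degree below 17 (inclusive bound, i.e. degree 17
survives — the smallest degree in the published top-10), bins the
remainder on d̂_essential with width 0.5 anchored at 0 (left-closed
right-open, reproducing the [1.0,1.5), [1.5,2.0) … intervals), sorts
within a bin by d̂_drug descending with ties broken by gene symbol, and
assigns ranks over the concatenated bins.  Feeding the ten published
(d̂_E, d̂_D, degree) tuples through this procedure reproduces the
published row order exactly, which is the strongest available check of
the reconstruction.  Whether candidates with d̂_essential < 1 were
excluded upstream in the original ranking is unknowable from the text;
none of the published rows is below 1, and the implementation ranks them
normally (they land in the lowest bins).

## Synthetic data generator

The generator emulates the study's inputs, not any repository's schema:

* **Interactome** — Barabási–Albert preferential attachment (connected,
  simple, heavy-tailed); chosen over duplication-divergence for speed and
  a controllable tail.  Node labels are zero-padded synthetic symbols
  ("G000001"…), giving stable lexicographic tie-breaks.  Default
  n = 2000, m = 3.
* **Markers** — essential genes sampled with degree-proportional weights
  (the empirical hub–lethality association; it also makes strong
  essential fields reachable on synthetic data); drug targets and
  disease genes uniform; bioassay targets sampled with odds multiplied by
  ρ (`proximity_rho`) for proteins within distance 1 of an essential
  gene.  ρ = 1 is the exact uniform null; the default ρ = 5 plants a
  clearly detectable signal.  Bioassay targets are disjoint from drug
  targets by default, because the prioritisation ranks targets that are
  *not yet* drugged; `allow_overlap=True` lifts this.  Weighted sampling
  without replacement uses Efraimidis–Spirakis keys, so every set is a
  pure function of the seed.
* **Activity table** — assays round-robin over clusters, compounds
  round-robin home clusters; a pair is active with probability `p_in`
  within a cluster and `p_out` across (defaults 0.30/0.005), so the
  Jaccard projection has community structure.  A `target_based_frac`
  (default 0.52) of assays is marked target-based and assigned a target
  symbol drawn from the bioassay-target set.  The degenerate
  `p_in = p_out` (including all-zero) configurations are allowed for
  edge-case testing; only `p_out > p_in` is rejected.

**Default scales.**  Counts are scaled to roughly one tenth of the
~20k-protein study the pipeline is designed for (130 drug targets, 170
disease genes, 60-assay screen), with two deliberate departures.
Bioassay targets default to 60 rather than a strictly proportional ~22,
so per-shell fractions are estimable.  Essential genes default to 60
rather than ~240: because essential genes are degree-biased hubs, a
proportional essential set's distance-1 neighbourhood would blanket
roughly three quarters of a 2000-node preferential-attachment graph —
at that coverage a distance-≤1 planting rule has almost no room to
distinguish planted from uniform proteins, and the generator could not
honour its own contract that planted enrichment (ρ ≥ 5) is recoverable
with ≥ 90% power.  At 60 essential genes the neighbourhood covers about
a third of the proteome and the planted signal is recoverable with wide
margin.  This is a property of desk-scale preferential-attachment
graphs, whose hub neighbourhoods are proportionally far larger than a
real interactome's; it is one of the ways the synthetic study is *not* a
miniature of real data.

**What passing tests show.**  The generator demonstrates that the
pipeline recovers planted proximity structure and is calibrated under
its own null.  It does not emulate screening-assay outcome noise,
activity-score normalisation, interactome ascertainment bias, or
literature-derived marker curation, so passing tests say nothing about
those failure modes on real data.

## Calibration

`validation.type_i_error_rate` redraws null markers (ρ = 1) and a uniform
seed set per replicate — seeds and control draws are then exchangeable,
so the rejection rate of the distance-1 p-value at α = 0.05 estimates the
test's size (measured 0.035–0.06 over 200 replicates across seeds; the
99% binomial band around 5% is [0.0105, 0.0895]).
`validation.detection_power` redraws planted markers (default ρ = 10) and
runs the real analysis (seeds = essential genes); measured power at
α = 0.01 is ≥ 0.96 across seeds with 1,000 control draws per replicate.
Replicate counts (200 null / 25 planted) and the 1,000-draw control
follow the desk-scale study design; the planted-vs-uniform
characteristic-distance comparison pools four marker replicates
(240 values per group) because a single 60-vs-60 draw is an unnecessarily
noisy measurement of a systematic effect.

## Numerical and degenerate-input conventions

* Jaccard of two empty sets, summaries of empty networks, degree
  distributions/clustering of empty graphs, enrichment with empty seeds
  or markers, and a charge profile whose charged set is only the target
  all raise `ValueError` rather than returning sentinels.
* d̂ = +∞ when no charged member is reachable; such rows are dropped by
  the prioritisation (they cannot be binned).
* p-values are never exactly 0; the normal tail underflows at ~1e-320
  and the acceptance report caps log₁₀p at −320.
* All RNG flows through `numpy.random.default_rng` seeded from explicit
  config values; generator sub-streams use seed sequences
  `[seed, stage]` so stages are independently reproducible.

## Known limitations

* The characteristic-distance formula is a reconstruction (see above);
  alternative formulas satisfying only the analogy loosely (e.g.
  E^(−1) or a min-distance rule) are excluded by the single-shell
  identity and the published value ranges, but cannot be excluded with
  certainty.
* The degree-17 candidate filter is calibrated to a ~20k-protein,
  250k-edge interactome; on the sparser synthetic default (mean degree
  ≈ 6) it retains only the handful of hub candidates.  The analysis
  drivers keep the published default; studies on sparse networks should
  scale `min_degree` down.
* OLS log-log fitting of degree distributions is statistically crude
  (it is used here because it is what the r/R² reporting convention
  implies); no maximum-likelihood tail estimation is provided.
* Published snapshot-dependent quantities (network node/edge counts,
  fitted exponents, the 5.28%/3.94% distance-1 fractions) are context
  for the method, not reproducible targets at synthetic scale.
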