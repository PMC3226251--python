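# assaynet

Network analysis of high-throughput chemical-screening data, for
computational biologists asking whether the protein targets chosen for
public bioassay screens are promising future drug targets.

Screening repositories record which compounds were active in which
bioassays.  `assaynet` organises those records as a bipartite
assay–compound network, projects it onto assays by compound-set
similarity, measures how the screened protein targets distribute through
a protein–protein interaction (PPI) network relative to essential genes,
approved drug targets and disease genes, and converts that distribution
into a quantitative druggability ranking.

## The model

**Bioassay network.**  Assays *u*, *v* with active-compound sets
*A(u)*, *A(v)* are connected when their Jaccard coefficient
*J* = |*A(u)* ∩ *A(v)*| / |*A(u)* ∪ *A(v)*| is at least 0.10 ("share at
least 10% of active compounds"); *J* is the edge weight.  Scale-free
structure is diagnosed by an OLS fit of log₁₀ *P*(*k*) on log₁₀ *k*, and
hierarchy by the degree dependence of the clustering coefficient
*C<sub>i</sub>* = 2*n* / [*k<sub>i</sub>*(*k<sub>i</sub>* − 1)], with *n*
the number of links among the *k<sub>i</sub>* neighbours of node *i*.

**Proximity enrichment.**  For each anchor protein (an essential gene,
drug target or disease gene) the shortest-path shells around it are
scanned and the fraction of shell members that are bioassay targets is
recorded; the mean profile over anchors is compared with the same profile
around randomly drawn proteins, per distance, with a two-sided Wilcoxon
rank-sum test.

**Characteristic distance.**  Each member of a marker set is treated as a
unit charge with an inverse-square field.  With *f<sub>i</sub>* the
fraction of the set at shortest-path distance *d<sub>i</sub>* from a
candidate protein, the accumulated field is
*E* = Σ<sub>i</sub> *f<sub>i</sub>* / *d<sub>i</sub>*², and the
characteristic distance is **d̂ = E<sup>−1/2</sup>** — the distance at
which one unit charge would produce the same field.  All mass on one
shell at distance *k* gives d̂ = *k* exactly; d̂ < 1 requires strong
concentration inside the first shell.

**Prioritisation.**  Candidates (bioassay targets that are not already
drug targets) are binned on d̂ to the essential genes (width 0.5,
ascending — closer to essentiality first), ranked within each bin by d̂
to the drug targets *descending* (farther from the existing target
repertoire = more novel), and filtered to degree ≥ 17 in the PPI network.

Because public screening snapshots and interaction databases change
continuously, the package ships a synthetic-data module that generates
the full study — a preferential-attachment interactome, marker sets with
a planted proximity signal of tunable strength ρ, and a clustered
activity table — so every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_data.py
python analysis/02_assay_network.py
python analysis/03_target_neighborhood.py
python analysis/04_prioritize_targets.py
```

The first script generates the synthetic study (2,000 proteins, 60-assay
screen) and prints its scale:

```
interactome: 2000 proteins, 5991 interactions
markers: 60 essential, 130 drug targets, 170 disease genes, 60 bioassay targets (proximity rho = 5.0)
screen: 1973 active pairs over 60 assays and 595 compounds (32.9 compounds/assay, 3.3 assays/compound)
```

The network characterisation finds the clustered projection and the flat
clustering profile that marks a non-hierarchical network:

```
assay projection (Jaccard >= 0.10): 60 nodes, 241 edges, diameter 2
clustering coefficient: mean 0.89 (sd 0.06)
C(k) log-log slope -0.01 -> not hierarchical
```

The neighbourhood analysis recovers the planted proximity signal — at
distance 1 from an essential gene, bioassay targets are over-represented
relative to the randomised control — and the prioritisation turns the
characteristic distances into a ranked table:

```
around essential: 5.14% of distance-1 proteins are bioassay targets vs 4.06% around random proteins (P = 0.0102)
...
rank  gene     d_essential  d_drug  degree
1     G000007  1.9638       2.3163  90
2     G000089  2.2712       2.8573  22
```

A smaller `d_essential` means the candidate sits in a denser essential-
gene field; within a bin, a larger `d_drug` means it is farther from all
existing drug targets, i.e. a more novel candidate.  The same pipeline
runs as a single command (`assaynet all --seed 0 --out results/run`), or
on real TSV inputs via the `inputs:` block documented in
`configs/default.yaml`.

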