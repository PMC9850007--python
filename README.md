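# coocnet

Co-occurrence network analysis of microbiome OTU tables: Spearman
correlation networks, topology and modularity, Zi–Pi node roles,
keystone and rare/abundant taxa, and between-network dissimilarity.

## What problem this solves

Gut-microbiome surveys (for example multi-population 16S rRNA studies
of wild and captive animals) routinely ask how taxa *interact*, not
just which taxa are present. The standard answer is a co-occurrence
network: nodes are OTUs, and an edge connects two OTUs whose abundances
co-vary strongly and significantly across samples. The structure of
that graph — its modules, its hubs and connectors, its keystone taxa,
and how its wiring differs between populations — is the object of
study. `coocnet` implements that whole analysis as a tested, reusable
Python library for microbial ecologists, plus a synthetic OTU-table
generator with planted structure so every stage can be validated
without access to raw sequencing data.

## The method

Given a samples × OTUs count table with sample group labels:

1. **Abundance.** Per-sample proportions; an OTU's relative abundance
   is the mean proportion over the samples in scope. Classes: *rare*
   (< 0.01 %), *abundant* (> 0.1 %), *moderate* (between, inclusive).
2. **Network.** The top-*N* (default 1000) most abundant OTUs enter;
   all pairwise Spearman rank correlations ρ are computed with
   two-sided p-values from the t approximation
   t = ρ√((n−2)/(1−ρ²)); an edge is kept iff |ρ| ≥ 0.6 and p ≤ 0.05
   (both inclusive). Edges are signed by the direction of ρ; isolated
   OTUs are dropped.
3. **Topology.** Degree, raw betweenness centrality (unordered-pair
   counts), component-corrected closeness, and max-normalized
   eigenvector centrality per node; Mann–Whitney U tests compare
   node-feature distributions between networks.
4. **Modules.** Greedy (CNM) modularity maximization with one local
   refinement pass; Newman's Q = Σ_s [l_s/L − (d_s/2L)²]; major
   modules have more than 10 nodes.
5. **Roles.** Within-module connectivity Zi (z-score of within-module
   degree) and participation coefficient Pi = 1 − Σ_m (κ_im/k_i)².
   Thresholds Zi > 2.5 and Pi > 0.62 split nodes into network hubs,
   module hubs, connectors and peripheral nodes. Keystone taxa have
   degree > 50 and betweenness < 5000.
6. **Network dissimilarity.** From shared edges a and unique edges
   b, c: Whittaker's β_w = (a+b+c)/((2a+b+c)/2) − 1 ∈ [0, 1].

The synthetic generator draws log-normal baseline abundances, plants
modules as blocks of OTUs sharing a latent per-sample factor (with
designated hubs carrying the largest loadings and connectors loading on
two modules), adds log-scale Gaussian noise, and renders counts by
multinomial sampling at fixed sequencing depth.

## Worked example

```bash
python examples/modules_and_roles.py
```

builds a 500-OTU, 160-sample synthetic cohort with four planted
15-OTU modules, thresholds its Spearman correlations at |ρ| ≥ 0.6 and
p ≤ 0.05, and prints:

```
4 modules, Q = 0.693, major (>10 nodes): [1, 2, 3, 4]
role counts: {'peripheral': 59, 'module_hub': 4}
highest within-module connectivity (Zi):
  OTU_0089: Zi=3.07 Pi=0.26 (planted hub)
  OTU_0432: Zi=2.91 Pi=0.00 (planted hub)
  OTU_0281: Zi=2.74 Pi=0.12 (planted hub)
  OTU_0086: Zi=2.71 Pi=0.12 (planted hub)
keystone OTUs (degree>50, betweenness<5000): 0
```

Reading this: module detection recovered the four planted blocks
cleanly (Q ≈ 0.7 means the graph separates well into modules), and the
four nodes with the highest within-module connectivity are exactly the
four planted hubs — the generator's designated best-connected members.
No node clears the keystone degree cutoff because a 15-OTU module
cannot produce degree > 50; keystones appear at full study scale.

The other scripts in `examples/` cover table simulation, network
construction, population comparisons and the one-call pipeline
(`run_all`), which writes every report table (per-network summary,
module membership and composition, roles, crosstabs, ternary
coordinates, dissimilarities) plus GraphML networks and a run log.

A CLI mirrors the library:

```bash
coocnet simulate --config sim.yaml --out-prefix demo
coocnet build --table demo_otus.tsv --metadata demo_metadata.tsv \
    --top-n 1000 --rho 0.6 --p 0.05 --out net.graphml
coocnet modules --net net.graphml --out modules.tsv
coocnet roles --net net.graphml --modules modules.tsv --out roles.tsv
coocnet compare-nets --a a.graphml --b b.graphml
coocnet run-all --config run.yaml
```

## Layout

```
src/coocnet/     library (io, abundance, conet, topology, community,
                 roles, netbeta, simulate, pipeline, cli)
examples/        one narrative script per capability
tests/           pytest suite incl. brute-force oracle batteries
scripts/         acceptance.py
docs/methods.md  modelling and design notes
```
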