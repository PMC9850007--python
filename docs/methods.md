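# Methods and design notes

This note documents the statistical conventions, the synthetic-data
model, and the design decisions behind `coocnet`, in the spirit of a
package vignette. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Relative abundance and taxon classes

An OTU's relative abundance is the arithmetic mean of its per-sample
proportions over the samples in scope — not the proportion of pooled
counts. The two differ when sequencing depth varies between samples;
the mean-of-proportions form weights every sample equally and is
invariant to uniform depth rescaling (a tested property). Classes are
cut at mean proportion 1e-4 and 1e-3 (0.01 % and 0.1 %): *rare* strictly
below 1e-4, *abundant* strictly above 1e-3, *moderate* inclusive of
both boundaries. Top-N selection for network construction ranks by the
same mean proportion, with ties broken by OTU id so the selection is
deterministic; the ranking basis is a deliberate choice exposed through
the profile object rather than a config flag.

## Correlation network

Spearman's ρ is Pearson correlation on average ranks, computed for all
pairs at once via rank transformation and a matrix product. Two-sided
p-values use the conventional t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom, with p = 0 at |ρ| = 1.
An exact full-permutation p-value is available for ≤ 10 samples; at
n = 5 the approximation can deviate from the exact null by about 0.1,
which the tests document. A constant (all-tied) abundance vector has no
defined rank correlation; its pairs are recorded as ρ = 0, p = 1 (with
a warning) so degenerate OTUs can never create edges.

Edges require |ρ| ≥ rho_threshold (default 0.6) **and**
p ≤ p_threshold (default 0.05), both inclusive. No multiple-testing
correction is applied by default — with ~500 samples the |ρ| ≥ 0.6
requirement is far more stringent than p ≤ 0.05 — but a
Benjamini–Hochberg switch exists (`fdr=True`). The graph is undirected
and unweighted downstream; ρ, p and the sign survive only as edge
attributes. Rationale: integer-valued cutoffs on degree and betweenness
(the keystone rule) only make sense for edge counts.

## Centralities

* **degree** — incident edge count.
* **betweenness** — raw sums of σ_st(v)/σ_st over unordered pairs,
  *unnormalized*, because the keystone cutoff (< 5000) is an absolute
  number that normalized betweenness (≤ 1) could never reach on
  networks of a few hundred nodes. The normalized variant is emitted
  alongside in every table for cross-study comparison.
* **closeness** — the component-corrected form
  ((n_c−1)/(n−1)) · ((n_c−1)/Σd), which keeps values in [0, 1] on the
  disconnected graphs that thresholding typically produces.
* **eigenvector** — power iteration with a uniform start vector on
  A + I (same eigenvectors as A, strictly dominant leading eigenvalue,
  so bipartite components cannot oscillate), run to a 1e-13 successive-
  iterate tolerance and max-normalized. On disconnected graphs the
  dominant component wins and other components decay toward 0; this is
  the documented, deterministic convention.

Mann–Whitney U comparisons of node features use full enumeration of
group labelings (exact even under ties) when both samples have ≤ 8
values, and the tie- and continuity-corrected normal approximation
otherwise.

## Modules and modularity

Q = Σ_s [l_s/L − (d_s/2L)²], unweighted and blind to edge sign.
Negative edges are ordinary edges for this purpose: they are vanishingly
rare in the networks this package targets (a handful per thousands of
edges), and sign-aware modularity is out of scope. Detection is greedy
agglomerative merging (CNM, as implemented in networkx) followed by one
pass of local single-node moves accepting the best strictly positive
gain (ties to the smallest module id). The procedure is deterministic
for a fixed input graph; the `seed` parameter exists for interface
stability. Detected modules are relabeled 1..K by decreasing size (ties
by smallest member id); "major" modules are those with **more than**
`min_major_size` nodes (default 10, configurable because study-specific
cutoffs vary). On graphs small enough for exhaustive partition search
the detected Q is within 0.05 of the global optimum (tested), and it is
never below the trivial one-module or all-singletons partitions.

## Node roles and keystones

Zi standardizes a node's within-module link count over its module's
members using the *population* standard deviation (the convention of
the participation-coefficient framework); a module whose members all
have equal within-module degree has sd = 0 and gets Zi = 0 for all
members. Pi = 1 − Σ_m (κ_im/k_i)². Role thresholds are Zi > 2.5 (strict)
for hubs and Pi > 0.62 (strict) for connectors, so boundary values
(2.5, 0.62) are peripheral. Keystone status requires degree strictly
above 50 and raw betweenness strictly below 5000; both cutoffs are
parameters with those defaults.

## Network dissimilarity

With a shared and b, c unique edges, Whittaker's
β_w = (a+b+c)/((2a+b+c)/2) − 1, bounded in [0, 1]; a Jaccard distance
variant (1 − a/(a+b+c)) is available. Edge identity is the unordered
OTU-id pair only — sign and magnitude are ignored, since the comparison
is about which pairs co-occur at all. β_w is symmetric, and adding a
shared edge to both networks never increases it (tested properties).

## Synthetic data model

The generator emulates the *statistical shape* of a multi-population
16S survey, not its biology:

* **Abundance spectrum.** Per-OTU baselines are log-normal(μ, σ);
  σ = 2 (default) spans rare, moderate and abundant classes.
* **Planted modules.** Each of `n_modules` modules has one latent
  N(0, 1) factor per sample added (scaled) to members' log-abundances.
  The full loading λ is chosen so two full-loading members have latent
  log-scale correlation `intra_module_correlation` given the log-noise
  (λ = noise_sd·√(r/(1−r))). Regular members carry heterogeneous
  loadings (uniform 0.33–0.55 of λ): with homogeneous loadings a module
  at correlation 0.9 would be a clique at the 0.6 edge threshold and no
  member could be better connected than any other, which is neither
  realistic nor useful for testing hub detection. Hubs carry 1.4·λ (the
  module's largest loading, hence its best-connected member);
  connectors carry 1.2·λ on each of two modules (their own and the
  cyclically next). Because a connector loads *equally* on both
  modules, its "true" module is ambiguous by construction — recovery
  metrics therefore score the unambiguous planted members
  (`GroundTruth.unambiguous_otus`). The equal split is deliberate: any
  asymmetry strong enough to disambiguate pushes the weaker bridge
  correlation below the 0.6 threshold and the connector stops being a
  connector.
* **Placement.** Module membership is planted on high- but not
  top-baseline OTUs, capping the planted share of total community mass
  (5 %, shrinking further for loadings above 1.5). Taxa that dominate
  the composition would transmit their factor swings to every other
  taxon through the shared multinomial denominator and induce spurious
  background correlations — a compositional artifact the cap keeps
  far below the edge threshold while leaving planted OTUs abundant
  enough (hundreds of reads) that rank correlations survive counting
  noise.
* **Counts.** Independent N(0, noise_sd²) log-noise, then one
  multinomial draw per sample at `sequencing_depth`, so row sums are
  exact. All randomness flows from one generator seeded by
  `config.seed`; identical configs yield identical tables.
* **Taxonomy.** 7-rank lineages from a small fixed vocabulary, with
  each module biased toward one phylum so composition summaries have
  structure to find.

Defaults describe a three-population cohort of 207/139/148 samples,
3000 OTUs, 50,000 reads per sample, four modules of 20 OTUs at
intra-module correlation 0.9. Depth and OTU count are not dictated by
any particular study design and are exposed in the config.

What the generator does **not** emulate: compositional effects beyond
the shared denominator (no interaction terms), overdispersion beyond
log-normal × multinomial, sequencing error, chimeras, or phylogenetic
correlation between taxa. Passing recovery tests therefore shows the
pipeline recovers planted rank-correlation block structure at realistic
size and noise — not that any particular biological claim holds in
real data.

## Reporting conventions

Report percentages are rounded half-up to 2 decimals (so 65.625 %
prints as 65.63 %), matching how published summary tables are printed;
an empty network reports NaN rather than a fabricated percentage.
TSV outputs are UTF-8, tab-delimited, "." decimal. The run log records
stages, sizes and thresholds but no timestamps, so repeated runs with
the same config are byte-identical (a tested guarantee).

## Problem sizes in the test and acceptance runs

The oracle batteries use ≥ 200 randomized instances of ≤ 8-node graphs
and 10-sample tables — small enough for exhaustive/brute-force
references, large enough in number to exercise tie and disconnection
edge cases. The recovery run uses the full default cohort (494 samples,
3000 OTUs); smaller cohorts (≈ 250–600 OTUs, 130–160 samples) are used
where many pipeline runs are repeated, which keeps the whole suite
fast without changing any threshold or model parameter.

## Known limitations

* Spearman co-occurrence on proportions is not a compositional method
  (no SparCC/SPIEC-EASI-style correction); with the top-N restriction
  and a 0.6 threshold the compositional bias is small but not zero.
* Greedy modularity with one refinement pass can land in local optima
  on adversarial graphs (bounded at 0.05 from optimal only at ≤ 8
  nodes, by test).
* Exact Mann–Whitney enumeration is limited to 8 + 8 values; beyond
  that the normal approximation is used even when an exact method
  would be feasible.
* The Zi sd = 0 → Zi = 0 convention makes tiny modules' hubs invisible
  to Zi-based criteria; this matches the framework the thresholds come
  from but should be kept in mind for modules of fewer than ~5 nodes.
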