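"""Compare co-occurrence networks between populations.

Two networks over the same OTU universe are compared through their edge
sets: shared edges (a), edges unique to each network (b, c), and the
Whittaker turnover index beta_w = (a+b+c)/((2a+b+c)/2) - 1, which is 0
for identical and 1 for fully disjoint wiring.  Node-level centrality
distributions are compared with a Mann-Whitney U test.
"""

import warnings

from coocnet import (
    SimulationConfig,
    build_network,
    compare_feature,
    network_dissimilarity,
    node_topology,
    relative_abundance,
    select_top_otus,
    simulate_otu_table,
    spearman_matrix,
)

warnings.filterwarnings("ignore")

table, _ = simulate_otu_table(
    SimulationConfig(n_otus=500, samples_per_group=(80, 80, 80),
                     sequencing_depth=30_000, seed=42)
)

networks = {}
for group in table.group_names:
    sub = table.subset_group(group)
    profile = relative_abundance(sub)
    corr = spearman_matrix(sub, select_top_otus(profile, 300))
    networks[group] = build_network(corr, profile=profile)
    print(f"{group}: {networks[group].number_of_nodes()} nodes, "
          f"{networks[group].number_of_edges()} edges")

g1, g2 = table.group_names[:2]
cmp = network_dissimilarity(networks[g1], networks[g2])
print(f"{g1} vs {g2}: shared={cmp.shared_edges} "
      f"unique={cmp.unique_to_first}/{cmp.unique_to_second} "
      f"beta_w={cmp.dissimilarity:.3f}")

deg1 = node_topology(networks[g1])["degree"]
deg2 = node_topology(networks[g2])["degree"]
u, p = compare_feature(deg1, deg2)
print(f"degree distributions: U={u:.0f}, p={p:.3g}")

# The same modules are planted in every group here, so much of the
# wiring is shared (beta_w well below 1) and the degree distributions
# are statistically indistinguishable.  With real populations, habitat
# differences surface as high turnover and shifted centralities.
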