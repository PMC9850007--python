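"""Detect modules, classify node roles in the Zi-Pi plane, and flag
keystone taxa.

Modules are communities found by greedy modularity maximization.  Each
node then gets a within-module connectivity z-score (Zi) and a
participation coefficient over modules (Pi); thresholds Zi > 2.5 and
Pi > 0.62 cut the plane into network hubs, module hubs, connectors and
peripheral nodes.  Keystone taxa are highly connected nodes (degree >
50) that are not mere bridges (betweenness < 5000).
"""

import warnings

from coocnet import (
    SimulationConfig,
    build_network,
    detect_modules,
    keystone_flags,
    node_topology,
    relative_abundance,
    role_table,
    select_top_otus,
    simulate_otu_table,
    spearman_matrix,
)

warnings.filterwarnings("ignore")

table, truth = simulate_otu_table(
    SimulationConfig(n_otus=500, samples_per_group=(60, 50, 50),
                     sequencing_depth=30_000, seed=42)
)
profile = relative_abundance(table)
corr = spearman_matrix(table, select_top_otus(profile, 300))
net = build_network(corr, profile=profile, taxonomy=table.taxonomy)

part = detect_modules(net, min_major_size=10)
print(f"{part.n_modules} modules, Q = {part.modularity_q:.3f}, "
      f"major (>10 nodes): {part.major_modules}")

topo = node_topology(net)
roles = role_table(net, part, topo)
print("role counts:", roles["role"].value_counts().to_dict())

top_zi = roles.sort_values("zi", ascending=False).head(4)
print("highest within-module connectivity (Zi):")
for otu, row in top_zi.iterrows():
    tag = "planted hub" if otu in truth.planted_hubs else "member"
    print(f"  {otu}: Zi={row.zi:.2f} Pi={row.pi:.2f} ({tag})")

keystones = keystone_flags(topo, degree_min=50, betweenness_max=5000)
print(f"keystone OTUs (degree>50, betweenness<5000): {len(keystones)}")

# The top-Zi nodes are the planted hubs: they carry the largest factor
# loading of their module, so they are the best-connected members.  The
# modularity Q near 0.7 says the correlation graph splits cleanly into
# the planted blocks.
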