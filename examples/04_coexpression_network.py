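"""Weighted co-expression network over development time.

Soft-threshold adjacency |cor|^beta on log2(FPKM+1), topological overlap,
average-linkage module detection, module eigengenes, Spearman module-trait
correlation against development-time rank, intramodular connectivity and
hub calls.
"""

import warnings

from lincscan import NetworkConfig, SimulationConfig, build_network
from lincscan.synthetic_data import simulate_expression, simulate_genome
from lincscan.workflow import development_traits

warnings.simplefilter("ignore")

config = SimulationConfig(seed=0)
scene = simulate_genome(config)
_, dev_matrix = simulate_expression(scene.truth, config)

net = build_network(
    dev_matrix.values,
    development_traits(dev_matrix),
    NetworkConfig(hub_percentile=0.05),
    linc_ids=set(scene.truth.planted_linc_ids),
)

print(f"soft power: {net.beta}")
for mod in net.modules:
    rho, p = mod.trait_correlations["time_order"]
    print(
        f"module {mod.label:>10}: {len(mod.member_ids):3d} members, "
        f"rho(time_order) = {rho:+.2f} (p = {p:.2g}), "
        f"trait-related = {mod.flagged_trait_related}, hubs = {mod.hubs}"
    )
print("lincRNAs directly connected to hub genes:", sorted(net.linked_lincs))
# Each detected module tracks one planted monotone eigen-profile; modules
# with |rho| >= 0.6 and p < 0.01 against a development trait are flagged, and
# hub genes are the top 5% of members by intramodular connectivity.
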