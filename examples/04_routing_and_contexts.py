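"""Routing-network interpretation and CpG-context enrichment.

Trains the capsule network, averages the per-sample routing coefficients
into a gene-to-class bipartite graph, projects it to a gene-gene correlation
network, and clusters it with Louvain modularity. Then ranks CpG weights
from the sparse pathway network, tests the top set for enrichment in a
genomic context with Fisher's exact test, and derives the bimodal
beta-value methylation threshold.
"""

import numpy as np
import pandas as pd

from methylcaps.capsnet import capsnet_forward
from methylcaps.interpret import (
    average_routing,
    beta_bimodal_threshold,
    bipartite_to_unipartite,
    context_enrichment,
    louvain_modules,
)
from methylcaps.simulate import SimulationSpec, simulate_dataset
from methylcaps.spwnet import cpg_weight_ranking
from methylcaps.training import split_train_val_test, train_model

arr, cmap, truth = simulate_dataset(SimulationSpec(seed=3))
train, val, test = split_train_val_test(arr, seed=3)

model, _ = train_model(
    "capsnet", train, val, cmap, {"epochs": 30, "lr": 2e-3, "batch_size": 64}, seed=3
)
fwd = capsnet_forward(test, cmap, model)

routing = average_routing(fwd["C"], cmap.names, model.classes)
print("averaged gene-to-class routing (first 5 genes):")
print(routing.weights.head().round(3).to_string())

net = bipartite_to_unipartite(fwd["C"], cmap.names)
modules = louvain_modules(net, seed=3)
print("routing-network modules:", modules.value_counts().to_dict())

spw, _ = train_model(
    "spwnet", train, val, cmap, {"epochs": 60, "lr": 5e-3, "lambda_group": 1e-3}, seed=3
)
ranking = cpg_weight_ranking(spw).set_index("cpg")
signal_cpgs = {c for cap in truth.signal_capsules for c in cmap.capsules[cap]}
context = pd.Series(
    [c in signal_cpgs for c in ranking.index], index=ranking.index, name="signal"
)
enr = context_enrichment(ranking["weight"], context, top_k=50, direction="absolute")
print(f"top-50 |weight| CpGs vs signal-capsule membership: "
      f"OR = {enr['odds_ratio']:.2f}, p = {enr['p_value']:.2e}")

thr = beta_bimodal_threshold(arr.beta.to_numpy().ravel()[:5000])
frac = float((arr.beta.to_numpy() > thr).mean())
print(f"bimodal beta threshold = {thr:.3f}; "
      f"{frac:.1%} of site measurements called methylated")
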