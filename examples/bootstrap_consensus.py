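"""Bootstrap edge frequencies and grow a consensus network.

A pheno-centric network is learned on each bootstrap resample of the data;
each edge's inclusion fraction across resamples measures its stability.  The
consensus network is then grown edge by edge in descending frequency, printing
cross-validated AUC after each addition — the point where the curve flattens
is the natural place to stop adding predictors.
"""

from cgbn import SearchConfig, bootstrap_networks, consensus_network
from cgbn.simulate import GeneratorConfig, random_cgbn, sample_dataset

net = random_cgbn(GeneratorConfig(n_discrete=3, n_continuous=8, edge_prob=0.35, seed=11))
data = sample_dataset(net, 200, seed=12)

cfg = SearchConfig(algorithm="pheno_centric", phenotype="phenotype")
table = bootstrap_networks(data, cfg, B=25, seed=0)
print(f"bootstrap over B={table.B} resamples found {len(table.frequencies)} distinct edges")
print("top edges by inclusion fraction:")
for (parent, child), freq in table.ranked()[:5]:
    print(f"  {parent} -> {child}: {freq:.2f}")

print("\nconsensus growth (edge added, bootstrap frequency, pooled CV AUC):")
for i, step in enumerate(
    consensus_network(table, data, "phenotype", max_edges=6, config=cfg, seed=0), 1
):
    print(f"  {i}. {step.edge[0]} -> {step.edge[1]}  freq {step.frequency:.2f}  "
          f"CV AUC {step.cv_auc:.3f}")
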