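"""Simulate a mixed-data case-control study, learn a network with each search
algorithm, and evaluate phenotype prediction on held-out data.

The AUC printed for each algorithm is the probability that a random case
receives a higher predicted case-probability than a random control on the
independent test set; 0.5 is chance, 1.0 is perfect ranking.
"""

from cgbn import (
    GeneratorConfig,
    PriorHyper,
    SearchConfig,
    fit_parameters,
    learn_structure,
    markov_blanket,
    predict_dataset,
    random_cgbn,
    roc_auc,
    sample_dataset,
)

net = random_cgbn(GeneratorConfig(n_discrete=5, n_continuous=10, edge_prob=0.4, seed=42))
train = sample_dataset(net, 300, seed=1)
test = sample_dataset(net, 500, seed=2)
print(f"true network: {len(net.structure.edges)} edges, "
      f"phenotype blanket {sorted(markov_blanket(net.structure, 'phenotype'))}")

for algorithm in ("k2", "greedy", "pheno_centric", "annealing"):
    cfg = SearchConfig(algorithm=algorithm, prior=PriorHyper(), phenotype="phenotype", seed=0)
    structure = learn_structure(train, cfg)
    fitted = fit_parameters(structure, train, cfg.prior)
    result = predict_dataset(fitted, test)
    auc = roc_auc(result.probabilities[:, -1], test.codes("phenotype")).auc
    blanket = sorted(markov_blanket(structure, "phenotype"))
    print(f"{algorithm:>14}: {len(structure.edges):2d} edges, test AUC {auc:.3f}, "
          f"blanket {blanket}")
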