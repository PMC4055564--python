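# cgbn — conditional Gaussian Bayesian networks for mixed-data phenotype prediction

`cgbn` learns, validates and predicts with **conditional Gaussian Bayesian
networks (CGBNs)**: directed acyclic graphical models over a mix of discrete
and continuous variables, built for case-control studies in genomics and
metabolomics where a discrete phenotype must be predicted from multimodal
measurements (SNPs, expression, metabolite levels, clinical covariates)
*without discretizing the continuous data first*.

## The model

A CGBN is a DAG in which each discrete node `D` carries a conditional
probability table P(D | discrete parents), and each continuous node `X` is
Gaussian with mean linear in its continuous parents and parameters switched
by the joint state `j` of its discrete parents:

    X | pa(X), j  ~  N( β0_j + β_jᵀ x_pa ,  σ²_j )

Edges from continuous into discrete nodes are forbidden; this restriction is
what keeps exact inference available. Everything is scored by the Bayesian
marginal likelihood: discrete families with the BDeu Dirichlet-multinomial
score (equivalent sample size α spread uniformly over CPT cells), continuous
families with a conjugate normal–inverse-gamma Bayesian regression per
discrete-parent configuration. The network score is the sum of family scores,
so structure search is fully decomposable.

The package provides:

* four structure searches — K2 ordered search with add-triggers-remove
  stepwise swaps, greedy exhaustive hill-climbing (optional backtracking),
  pheno-centric Markov-blanket search, and simulated annealing;
* exact inference — posterior P(phenotype | evidence) by analytic Gaussian
  marginalization with enumeration of only the relevant hidden discrete
  configurations (equivalent in result to conditional-Gaussian junction-tree
  propagation), with a fast exact path when the full Markov blanket is
  observed;
* Bayes-factor variable screening for very wide datasets;
* validation machinery — Mann-Whitney AUC with convex-hull AUC and DeLong 95%
  CI, the DeLong paired-AUC test, stratified cross-validation with prior
  hyperparameter tuning, bootstrap edge frequencies and consensus networks;
* a synthetic-data engine (random CGBNs, forward sampling, 10-bin equal-width
  discretization) used by the test suite and the reproduction experiments;
* readers/writers for mixed delimited tables and PED SNP files, network
  export to TGF/SIF/GraphML, a JSON round trip for fitted networks, and a
  thin `cgbn` command-line interface.

## Worked example

`examples/discretization_cost.py` simulates three random networks of
5 discrete + 15 continuous variables, trains on only 25 records, and compares
learning from raw mixed data against learning after 10-bin equal-width
discretization:

```
network 101: mixed-data AUC 0.851  discretized AUC 0.851  (true blanket 10 nodes)
network 102: mixed-data AUC 0.996  discretized AUC 0.869  (true blanket 16 nodes)
network 103: mixed-data AUC 0.821  discretized AUC 0.586  (true blanket 10 nodes)

mean over 3 networks: 0.889 vs 0.768 -> discretization costs 12.1 AUC points
```

Each AUC is the probability that a random case outranks a random control on
an independent 200-record test set. Binning the continuous columns fragments
the data — a 10-state variable learned from 25 rows leaves ~2 rows per
parameter — so the discretized networks either miss informative edges or
estimate them poorly, and prediction suffers accordingly. The other scripts
in `examples/` each demonstrate one capability (screening, cross-validation
and tuning, bootstrap consensus, the four searches) on data they simulate
themselves.

A shell session looks like:

```sh
cgbn simulate --n-disc 5 --n-cont 15 --n-train 100 --seed 7 --out-prefix demo
cgbn learn   --data demo_train.csv --algorithm greedy --seed 7 --out demo_net.json
cgbn predict --net demo_net.json --data demo_test.csv
```

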