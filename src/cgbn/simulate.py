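"""Synthetic-data engine: random CGBN generation, forward sampling, and
equal-width discretization.

The generator emulates the case-control study design the package targets: a
binary phenotype placed first in a random node permutation (so it can parent
nodes of both kinds and never takes parents itself), candidate edges drawn
only forward along the permutation (acyclic by construction) and never from a
continuous node into a discrete one.  Discrete CPT rows are symmetric
Dirichlet(1) draws; continuous nodes get configuration-specific intercepts
spread apart to create class signal, coefficients of random sign with
magnitude drawn from ``effect_range``, and residual variances uniform on
[0.5, 1.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CONTINUOUS,
    DISCRETE,
    CGBayesNet,
    CLGNodeParams,
    DAGStructure,
    DiscreteNodeParams,
    MixedDataset,
    VariableSpec,
)

PHENOTYPE = "phenotype"


@dataclass
class GeneratorConfig:
    """Study conditions for the random-network generator.

    n_discrete includes the binary phenotype.  ``effect_range`` bounds both
    the continuous-parent coefficient magnitudes and the spacing between the
    configuration-specific intercepts of a continuous node with discrete
    parents (the class-signal mechanism).
    """

    n_discrete: int = 5
    n_continuous: int = 15
    n_states: int = 2
    max_parents: int = 3
    edge_prob: float = 0.25
    effect_range: tuple[float, float] = (1.0, 3.0)
    sigma_sq_range: tuple[float, float] = (0.5, 1.5)
    balanced_phenotype: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discrete < 1:
            raise ValueError("need at least the discrete phenotype")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")
        if self.n_states < 2:
            raise ValueError("discrete nodes need >= 2 states")


def _states(k: int) -> tuple[str, ...]:
    # non-numeric labels so delimited-table round trips re-infer the kind
    return tuple(f"s{i + 1}" for i in range(k))


def random_cgbn(cfg: GeneratorConfig) -> CGBayesNet:
    """Draw a random conditional Gaussian Bayesian network.

    The phenotype heads a random permutation of the remaining nodes; each
    later node keeps each legal earlier node as a parent with probability
    ``edge_prob``, down-sampled to ``max_parents`` when over the limit.
    """
    rng = np.random.default_rng(cfg.seed)
    disc_names = [PHENOTYPE] + [f"D{i}" for i in range(2, cfg.n_discrete + 1)]
    cont_names = [f"C{i}" for i in range(1, cfg.n_continuous + 1)]
    variables = [
        VariableSpec(PHENOTYPE, DISCRETE, ("ctrl", "case")),
        *(VariableSpec(n, DISCRETE, _states(cfg.n_states)) for n in disc_names[1:]),
        *(VariableSpec(n, CONTINUOUS) for n in cont_names),
    ]
    spec = {v.name: v for v in variables}
    others = disc_names[1:] + cont_names
    rng.shuffle(others)
    order = [PHENOTYPE] + others

    structure = DAGStructure([v.name for v in variables])
    for pos, node in enumerate(order):
        legal = [
            p for p in order[:pos]
            if not (spec[p].kind == CONTINUOUS and spec[node].kind == DISCRETE)
        ]
        keep = [p for p in legal if rng.random() < cfg.edge_prob]
        if len(keep) > cfg.max_parents:
            keep = list(rng.choice(keep, size=cfg.max_parents, replace=False))
        for p in keep:
            structure.add_edge(p, node)

    params: dict[str, DiscreteNodeParams | CLGNodeParams] = {}
    for node in structure.nodes:
        disc_parents = tuple(sorted(p for p in structure.parents(node) if spec[p].kind == DISCRETE))
        cont_parents = tuple(sorted(p for p in structure.parents(node) if spec[p].kind == CONTINUOUS))
        q = int(np.prod([spec[p].n_states for p in disc_parents])) if disc_parents else 1
        if spec[node].kind == DISCRETE:
            r = spec[node].n_states
            if node == PHENOTYPE and cfg.balanced_phenotype:
                cpt = np.full((q, r), 1.0 / r)
            else:
                cpt = rng.dirichlet(np.ones(r), size=q)
            params[node] = DiscreteNodeParams(disc_parents, spec[node].states, cpt)
        else:
            m = len(cont_parents)
            lo, hi = cfg.effect_range
            coefs = rng.uniform(lo, hi, size=(q, m)) * rng.choice([-1.0, 1.0], size=(q, m))
            base = rng.uniform(-1.0, 1.0)
            if q > 1:
                sep = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                intercepts = base + (np.arange(q) - (q - 1) / 2.0) * sep
            else:
                intercepts = np.full(1, base)
            variances = rng.uniform(*cfg.sigma_sq_range, size=q)
            params[node] = CLGNodeParams(disc_parents, cont_parents, intercepts, coefs, variances)
    return CGBayesNet(structure, tuple(variables), params, phenotype=PHENOTYPE)


def sample_dataset(net: CGBayesNet, n: int, seed: int = 0) -> MixedDataset:
    """Forward-sample ``n`` complete records in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = net.structure.topological_order()
    columns: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for node in order:
        p = net.params[node]
        if isinstance(p, DiscreteNodeParams):
            disc_parents, states = p.parents, p.states
            j = np.zeros(n, dtype=np.int64)
            for parent in disc_parents:
                j = j * len(net.var(parent).states) + codes[parent]
            u = rng.random(n)
            cum = np.cumsum(p.cpt, axis=1)
            code = (u[:, None] > cum[j]).sum(axis=1)
            codes[node] = code
            columns[node] = np.array(states, dtype=object)[code]
        else:
            j = np.zeros(n, dtype=np.int64)
            for parent in p.disc_parents:
                j = j * len(net.var(parent).states) + codes[parent]
            mean = p.intercepts[j]
            for c, parent in enumerate(p.cont_parents):
                mean = mean + p.coefs[j, c] * columns[parent]
            columns[node] = mean + rng.standard_normal(n) * np.sqrt(p.variances[j])
    frame = pd.DataFrame({v.name: columns[v.name] for v in net.variables})
    return MixedDataset(frame, net.variables, net.phenotype or PHENOTYPE)


def discretize_equal_width(
    data: MixedDataset,
    bins: int = 10,
    edges: dict[str, tuple[float, float]] | None = None,
    states: dict[str, tuple[str, ...]] | None = None,
) -> tuple[MixedDataset, dict[str, tuple[float, float]], dict[str, tuple[str, ...]]]:
    """Bin every continuous column into ``bins`` equal-width discrete bins.

    Returns the discretized dataset plus the per-column (min, max) edges and
    observed-bin state lists, so a test set can be binned with the training
    set's edges.  Values map to bins 1..bins (the maximum to the last bin);
    out-of-range values clip to the extreme bins, and a bin unobserved in the
    fitting data maps to the nearest observed bin (ties to the lower bin).
    A constant column becomes a single-state column (warned in the log).
    """
    import logging

    if bins < 2:
        raise ValueError("bins must be >= 2")
    fitting = edges is None
    edges = dict(edges or {})
    states = dict(states or {})
    frame = data.frame.copy()
    specs = []
    for v in data.variables:
        if v.kind == DISCRETE:
            specs.append(v)
            continue
        x = data.values(v.name)
        if fitting:
            lo, hi = float(x.min()), float(x.max())
            edges[v.name] = (lo, hi)
        else:
            lo, hi = edges[v.name]
        if hi <= lo:
            logging.getLogger(__name__).warning(
                "constant column %r: single-state after discretization", v.name
            )
            bin_ids = np.ones(len(x), dtype=int)
        else:
            bin_ids = np.floor((x - lo) / (hi - lo) * bins).astype(int) + 1
            bin_ids = np.clip(bin_ids, 1, bins)
        if fitting:
            observed = tuple(str(b) for b in sorted(set(bin_ids)))
            states[v.name] = observed
        else:
            observed_int = np.array([int(s) for s in states[v.name]])
            # nearest observed training bin; ties resolve to the lower bin
            dist = np.abs(bin_ids[:, None] - observed_int[None, :])
            bin_ids = observed_int[np.argmin(dist, axis=1)]
        frame[v.name] = [str(b) for b in bin_ids]
        specs.append(VariableSpec(v.name, DISCRETE, states[v.name]))
    return MixedDataset(frame, specs, data.phenotype), edges, states
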