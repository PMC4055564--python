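"""Parameter learning and exact phenotype prediction in a fitted CGBN.

Prediction enumerates the joint configurations of the *relevant* unobserved
discrete nodes (after pruning barren nodes — unobserved non-ancestors of the
evidence and target, whose marginalization is exact) and, for each
configuration, handles the continuous subnetwork analytically: given a full
discrete configuration the continuous nodes are jointly Gaussian, so observed
continuous evidence contributes a multivariate-normal density and unobserved
continuous nodes marginalize out by dropping rows of the joint.  The result is
exact and equals conditional-Gaussian junction-tree propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .model import (
    CONTINUOUS,
    DISCRETE,
    CGBayesNet,
    CLGNodeParams,
    DAGStructure,
    DiscreteNodeParams,
    MixedDataset,
    validate_cg_constraints,
)
from .scoring import PriorHyper, _config_index

#: enumeration guard: refuse queries whose hidden discrete space exceeds this
MAX_CONFIGURATIONS = 2 ** 20


@dataclass
class PredictionResult:
    """Per-record posterior over the target's states."""

    states: tuple[str, ...]
    probabilities: np.ndarray  # (n_records, r)

    @property
    def predicted(self) -> list[str]:
        return [self.states[i] for i in np.argmax(self.probabilities, axis=1)]


def fit_parameters(
    structure: DAGStructure, data: MixedDataset, prior: PriorHyper | None = None
) -> CGBayesNet:
    """Posterior-mean parameters for a fixed structure.

    Discrete nodes: smoothed CPT rows p_jk = (N_jk + alpha/(r q)) / (N_j + alpha/q).
    Continuous nodes: per discrete-parent configuration, posterior mean of the
    normal–inverse-gamma regression (beta_n; variance b_n/(a_n-1) when a_n > 1,
    else b_n/a_n).  Configurations with no rows fall back to the prior
    (uniform CPT row; beta = 0, sigma^2 = sigma0_sq).
    """
    prior = prior or PriorHyper()
    viol = validate_cg_constraints(structure, data.variables)
    if viol:
        raise ValueError(f"continuous->discrete edges: {viol}")
    params: dict[str, DiscreteNodeParams | CLGNodeParams] = {}
    for node in structure.nodes:
        node_parents = structure.parents(node)
        disc_parents = tuple(sorted(p for p in node_parents if data.kind(p) == DISCRETE))
        cont_parents = tuple(sorted(p for p in node_parents if data.kind(p) == CONTINUOUS))
        idx, q = _config_index(data, disc_parents)
        if data.kind(node) == DISCRETE:
            r = data.var(node).n_states
            counts = np.bincount(idx * r + data.codes(node), minlength=q * r).reshape(q, r)
            a_jk = prior.alpha / (r * q)
            a_j = prior.alpha / q
            cpt = (counts + a_jk) / (counts.sum(axis=1, keepdims=True) + a_j)
            params[node] = DiscreteNodeParams(disc_parents, data.var(node).states, cpt, counts)
        else:
            y = data.values(node)
            X = np.column_stack([np.ones(data.n)] + [data.values(p) for p in cont_parents])
            m = len(cont_parents)
            intercepts = np.zeros(q)
            coefs = np.zeros((q, m))
            variances = np.full(q, prior.sigma0_sq)
            for j in range(q):
                mask = idx == j
                n_j = int(mask.sum())
                if n_j == 0:
                    continue
                yj, Xj = y[mask], X[mask]
                lam_n = prior.nu * np.eye(m + 1) + Xj.T @ Xj
                beta_n = np.linalg.solve(lam_n, Xj.T @ yj)
                a_n = (prior.nu + n_j) / 2.0
                b_n = 0.5 * (prior.nu * prior.sigma0_sq + yj @ yj - beta_n @ lam_n @ beta_n)
                intercepts[j] = beta_n[0]
                coefs[j] = beta_n[1:]
                variances[j] = b_n / (a_n - 1.0) if a_n > 1.0 else b_n / a_n
            params[node] = CLGNodeParams(disc_parents, cont_parents, intercepts, coefs, variances)
    return CGBayesNet(structure.copy(), data.variables, params, phenotype=data.phenotype)


def _disc_config_row(net: CGBayesNet, node: str, assign: Mapping[str, str]) -> int:
    """Row index of ``node``'s parameter table under a discrete assignment."""
    p = net.params[node]
    disc_parents = p.parents if isinstance(p, DiscreteNodeParams) else p.disc_parents
    j = 0
    for parent in disc_parents:
        states = net.var(parent).states
        j = j * len(states) + states.index(assign[parent])
    return j


def joint_log_density(net: CGBayesNet, assignment: Mapping[str, str | float]) -> float:
    """Log of the factorized joint density at a full assignment of all nodes."""
    missing = [n for n in net.structure.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment missing nodes: {missing}")
    total = 0.0
    for node in net.structure.nodes:
        p = net.params[node]
        j = _disc_config_row(net, node, assignment)
        if isinstance(p, DiscreteNodeParams):
            k = p.states.index(str(assignment[node]))
            total += np.log(p.cpt[j, k])
        else:
            x = float(assignment[node])
            mean = p.intercepts[j] + sum(
                c * float(assignment[q]) for c, q in zip(p.coefs[j], p.cont_parents)
            )
            var = p.variances[j]
            total += -0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var)
    return float(total)


def _gaussian_joint(
    net: CGBayesNet, cont_nodes: list[str], disc_assign: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Gaussian (mean, covariance) over ``cont_nodes`` for a fixed
    discrete configuration, built by topological propagation.

    ``cont_nodes`` must be closed under continuous parents and listed in
    topological order.
    """
    pos = {n: i for i, n in enumerate(cont_nodes)}
    k = len(cont_nodes)
    mu = np.zeros(k)
    cov = np.zeros((k, k))
    for node in cont_nodes:
        i = pos[node]
        p = net.params[node]
        assert isinstance(p, CLGNodeParams)
        j = _disc_config_row(net, node, disc_assign)
        pa = [pos[q] for q in p.cont_parents]
        beta = p.coefs[j]
        mu[i] = p.intercepts[j] + beta @ mu[pa]
        if pa:
            cross = beta @ cov[np.ix_(pa, range(k))]
            cov[i, :] = cross
            cov[:, i] = cross
            cov[i, i] = p.variances[j] + beta @ cov[np.ix_(pa, pa)] @ beta
        else:
            cov[i, i] = p.variances[j]
    return mu, cov


def _relevant_subset(net: CGBayesNet, keep: set[str]) -> list[str]:
    """Ancestral closure of ``keep`` in topological order (barren-node pruning)."""
    closed = set(keep)
    frontier = list(keep)
    while frontier:
        node = frontier.pop()
        for p in net.structure.parents(node):
            if p not in closed:
                closed.add(p)
                frontier.append(p)
    return [n for n in net.structure.topological_order() if n in closed]


def _log_local_density(net: CGBayesNet, node: str, assign: Mapping[str, str | float]) -> float:
    """ln p(node | parents) at a pointwise assignment of node and parents."""
    p = net.params[node]
    j = _disc_config_row(net, node, assign)
    if isinstance(p, DiscreteNodeParams):
        val = p.cpt[j, p.states.index(str(assign[node]))]
        return float(np.log(val)) if val > 0 else -np.inf
    x = float(assign[node])
    mean = p.intercepts[j] + sum(
        c * float(assign[q]) for c, q in zip(p.coefs[j], p.cont_parents)
    )
    var = p.variances[j]
    return float(-0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var))


def _blanket_posterior(
    net: CGBayesNet, evidence: Mapping[str, str | float], target: str
) -> np.ndarray:
    """Exact posterior when the target's full Markov blanket is observed.

    With parents, children and co-parents all assigned, the posterior
    factorizes over the target's own CPT and its children's local densities;
    no enumeration or Gaussian marginalization is needed.
    """
    from .model import markov_blanket

    states = net.var(target).states
    children = sorted(net.structure.children(target))
    log_w = np.zeros(len(states))
    for t_idx, t_state in enumerate(states):
        assign = dict(evidence)
        assign[target] = t_state
        lw = _log_local_density(net, target, assign)
        for c in children:
            lw += _log_local_density(net, c, assign)
        log_w[t_idx] = lw
    if not np.isfinite(log_w).any():
        raise ValueError("evidence has zero likelihood under every target state")
    post = np.exp(log_w - logsumexp(log_w))
    return post / post.sum()


def predict(
    net: CGBayesNet, evidence: Mapping[str, str | float], target: str
) -> np.ndarray:
    """Exact posterior P(target | evidence) over the target's states.

    ``evidence`` is a partial assignment; unobserved discrete nodes are
    enumerated, unobserved continuous nodes marginalized analytically.  When
    the target's entire Markov blanket is observed, the posterior factorizes
    over the blanket families and is computed directly (same exact result).
    """
    if net.kind(target) != DISCRETE:
        raise TypeError("target must be discrete")
    if target in evidence:
        raise ValueError("target cannot appear in the evidence")
    for name, value in evidence.items():
        spec = net.var(name)
        if spec.kind == DISCRETE and str(value) not in spec.states:
            raise ValueError(f"unseen state {value!r} for variable {name!r}")

    from .model import markov_blanket

    blanket = markov_blanket(net.structure, target)
    if all(b in evidence for b in blanket):
        return _blanket_posterior(net, evidence, target)

    retained = _relevant_subset(net, set(evidence) | {target})
    disc_nodes = [n for n in retained if net.kind(n) == DISCRETE]
    cont_nodes = [n for n in retained if net.kind(n) == CONTINUOUS]
    hidden_disc = [n for n in disc_nodes if n not in evidence and n != target]
    state_lists = [net.var(n).states for n in hidden_disc]
    n_configs = int(np.prod([len(s) for s in state_lists])) if state_lists else 1
    target_states = net.var(target).states
    if n_configs * len(target_states) > MAX_CONFIGURATIONS:
        raise RuntimeError(
            f"{n_configs * len(target_states)} hidden discrete configurations "
            f"exceed the exact-enumeration guard ({MAX_CONFIGURATIONS})"
        )

    obs_cont = [n for n in cont_nodes if n in evidence]
    obs_idx = [cont_nodes.index(n) for n in obs_cont]
    obs_vals = np.array([float(evidence[n]) for n in obs_cont])

    import itertools

    log_w = np.full(len(target_states), -np.inf)
    per_state: list[list[float]] = [[] for _ in target_states]
    for hidden_assign in itertools.product(*state_lists) if state_lists else [()]:
        base = {n: str(evidence[n]) for n in disc_nodes if n in evidence}
        base.update(dict(zip(hidden_disc, hidden_assign)))
        for t_idx, t_state in enumerate(target_states):
            assign = dict(base)
            assign[target] = t_state
            lw = 0.0
            for node in disc_nodes:
                p = net.params[node]
                assert isinstance(p, DiscreteNodeParams)
                j = _disc_config_row(net, node, assign)
                k = p.states.index(assign[node])
                val = p.cpt[j, k]
                if val <= 0.0:
                    lw = -np.inf
                    break
                lw += np.log(val)
            if np.isfinite(lw) and obs_cont:
                mu, cov = _gaussian_joint(net, cont_nodes, assign)
                lw += multivariate_normal.logpdf(
                    obs_vals, mean=mu[obs_idx], cov=cov[np.ix_(obs_idx, obs_idx)]
                )
            per_state[t_idx].append(lw)
    log_w = np.array([logsumexp(ws) if ws else -np.inf for ws in per_state])
    if not np.isfinite(log_w).any():
        raise ValueError("evidence has zero likelihood under every target state")
    post = np.exp(log_w - logsumexp(log_w))
    return post / post.sum()


def predict_dataset(
    net: CGBayesNet, data: MixedDataset, target: str | None = None
) -> PredictionResult:
    """Per-row posterior of the target using Markov-blanket evidence.

    Each row (minus the target) is used as evidence restricted to the target's
    Markov blanket; variables outside the blanket provably cannot alter the
    posterior once the blanket is fully observed.
    """
    from .model import markov_blanket

    target = target or net.phenotype
    if target is None:
        raise ValueError("no target given and the network has no phenotype")
    blanket = markov_blanket(net.structure, target)
    missing = [b for b in blanket if b not in data.names]
    if missing:
        raise ValueError(f"dataset lacks Markov-blanket column(s): {missing}")
    states = net.var(target).states
    probs = np.zeros((data.n, len(states)))
    for i in range(data.n):
        row = data.frame.iloc[i]
        evidence = {b: row[b] for b in blanket}
        probs[i] = predict(net, evidence, target)
    return PredictionResult(states, probs)
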