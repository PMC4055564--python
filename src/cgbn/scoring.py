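"""Bayesian marginal-likelihood family scores and Bayes-factor screening.

All scores are natural-log marginal likelihoods of one node's data given its
parents, so the network score is the sum over nodes (decomposable).

* Discrete child: BDeu — Dirichlet-multinomial marginal likelihood with a
  single equivalent sample size ``alpha`` spread uniformly over CPT cells
  (``alpha/(r*q)`` per cell, ``alpha/q`` per parent configuration).
* Continuous child: normal–inverse-gamma conjugate Bayesian linear regression
  of the child on (1, continuous parents), fitted independently within each
  discrete-parent configuration: beta ~ N(0, sigma^2/nu * I),
  sigma^2 ~ InvGamma(nu/2, nu*sigma0_sq/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .model import CONTINUOUS, DISCRETE, DAGStructure, MixedDataset, validate_cg_constraints


@dataclass(frozen=True)
class PriorHyper:
    """Prior hyperparameters shared by scoring and parameter fitting.

    alpha      BDeu equivalent sample size (total Dirichlet pseudo-count).
    nu         Gaussian coefficient-prior precision pseudo-count.
    sigma0_sq  prior scale of the residual variance.
    max_parents  per-node parent limit honoured by the structure searches.
    """

    alpha: float = 1.0
    nu: float = 1.0
    sigma0_sq: float = 1.0
    max_parents: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.nu <= 0 or self.sigma0_sq <= 0:
            raise ValueError("alpha, nu and sigma0_sq must be strictly positive")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")


@dataclass(frozen=True)
class FamilyScore:
    child: str
    parents: frozenset[str]
    log_marginal_likelihood: float


def _config_index(data: MixedDataset, disc_parents: Sequence[str]) -> tuple[np.ndarray, int]:
    """Row-major configuration index over parents sorted by name.

    Matches :func:`cgbn.model.parent_configurations`: first (alphabetically
    first) parent varies slowest.
    """
    parents = sorted(disc_parents)
    if not parents:
        return np.zeros(data.n, dtype=np.int64), 1
    q = 1
    idx = np.zeros(data.n, dtype=np.int64)
    for p in parents:
        r_p = data.var(p).n_states
        idx = idx * r_p + data.codes(p)
        q *= r_p
    return idx, q


def bdeu_family_score(
    data: MixedDataset,
    child: str,
    parents: Iterable[str],
    prior: PriorHyper,
) -> FamilyScore:
    """BDeu log marginal likelihood of a discrete child given discrete parents."""
    parents = sorted(set(parents))
    if data.kind(child) != DISCRETE:
        raise TypeError(f"BDeu child {child!r} must be discrete")
    for p in parents:
        if data.kind(p) != DISCRETE:
            raise TypeError(f"BDeu parent {p!r} must be discrete")
    if data.n < 1:
        raise ValueError("need at least one observation")
    r = data.var(child).n_states
    idx, q = _config_index(data, parents)
    counts = np.bincount(idx * r + data.codes(child), minlength=q * r).reshape(q, r)
    a_jk = prior.alpha / (r * q)
    a_j = prior.alpha / q
    n_j = counts.sum(axis=1)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )
    return FamilyScore(child, frozenset(parents), score)


def _nig_log_marginal(y: np.ndarray, X: np.ndarray, nu: float, sigma0_sq: float) -> float:
    """ln m(y) for y ~ N(X beta, sigma^2 I), beta ~ N(0, sigma^2/nu I),
    sigma^2 ~ InvGamma(nu/2, nu*sigma0_sq/2)."""
    n, d = X.shape
    a0 = nu / 2.0
    b0 = nu * sigma0_sq / 2.0
    lam0 = nu * np.eye(d)
    lam_n = lam0 + X.T @ X
    beta_n = np.linalg.solve(lam_n, X.T @ y)
    a_n = a0 + n / 2.0
    b_n = b0 + 0.5 * (y @ y - beta_n @ lam_n @ beta_n)
    sign0, logdet0 = np.linalg.slogdet(lam0)
    sign_n, logdet_n = np.linalg.slogdet(lam_n)
    return float(
        -n / 2.0 * np.log(2.0 * np.pi)
        + 0.5 * (logdet0 - logdet_n)
        + a0 * np.log(b0)
        - a_n * np.log(b_n)
        + gammaln(a_n)
        - gammaln(a0)
    )


def clg_family_score(
    data: MixedDataset,
    child: str,
    cont_parents: Iterable[str],
    disc_parents: Iterable[str],
    prior: PriorHyper,
) -> FamilyScore:
    """Conditional linear Gaussian log marginal likelihood of a continuous child.

    One independent normal–inverse-gamma Bayesian regression per discrete-
    parent configuration; empty configurations contribute 0 (the marginal
    likelihood of no data is 1).
    """
    cont_parents = sorted(set(cont_parents))
    disc_parents = sorted(set(disc_parents))
    if data.kind(child) != CONTINUOUS:
        raise TypeError(f"CLG child {child!r} must be continuous")
    for p in cont_parents:
        if data.kind(p) != CONTINUOUS:
            raise TypeError(f"continuous parent {p!r} is discrete")
    for p in disc_parents:
        if data.kind(p) != DISCRETE:
            raise TypeError(f"discrete parent {p!r} is continuous")
    if data.n < 1:
        raise ValueError("need at least one observation")
    y = data.values(child)
    Xfull = np.column_stack(
        [np.ones(data.n)] + [data.values(p) for p in cont_parents]
    )
    idx, q = _config_index(data, disc_parents)
    total = 0.0
    for j in range(q):
        mask = idx == j
        if not mask.any():
            continue
        total += _nig_log_marginal(y[mask], Xfull[mask], prior.nu, prior.sigma0_sq)
    return FamilyScore(child, frozenset(cont_parents) | frozenset(disc_parents), total)


def family_score(
    data: MixedDataset,
    child: str,
    parents: Iterable[str],
    prior: PriorHyper,
) -> float:
    """Dispatch to the BDeu or CLG family score based on the child's kind."""
    parents = set(parents)
    if data.kind(child) == DISCRETE:
        return bdeu_family_score(data, child, parents, prior).log_marginal_likelihood
    cont = {p for p in parents if data.kind(p) == CONTINUOUS}
    disc = parents - cont
    return clg_family_score(data, child, cont, disc, prior).log_marginal_likelihood


def network_score(structure: DAGStructure, data: MixedDataset, prior: PriorHyper) -> float:
    """Sum of family scores over all nodes (decomposable network score)."""
    viol = validate_cg_constraints(structure, data.variables)
    if viol:
        raise ValueError(f"continuous->discrete edges: {viol}")
    return sum(
        family_score(data, node, structure.parents(node), prior)
        for node in structure.nodes
    )


def bayes_factor_filter(
    data: MixedDataset,
    phenotype: str,
    candidates: Sequence[str],
    log_bf_threshold: float = 0.0,
    prior: PriorHyper | None = None,
) -> list[tuple[str, float]]:
    """Univariate screen by log Bayes factor of dependence on the phenotype.

    For each candidate v, log BF = score(v | phenotype) - score(v | nothing).
    Candidates with log BF > threshold are returned sorted descending by
    log BF, ties broken by name.
    """
    prior = prior or PriorHyper()
    if data.kind(phenotype) != DISCRETE:
        raise TypeError("phenotype must be discrete")
    if phenotype in candidates:
        raise ValueError("phenotype cannot be its own candidate")
    out = []
    for v in candidates:
        log_bf = family_score(data, v, {phenotype}, prior) - family_score(data, v, set(), prior)
        if log_bf > log_bf_threshold:
            out.append((v, log_bf))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
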