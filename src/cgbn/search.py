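"""Structure learning: K2-ordered search, greedy exhaustive hill-climbing,
pheno-centric Markov-blanket search, and simulated annealing.

All searches maximize the decomposable Bayesian network score (sum of family
marginal likelihoods), honour the conditional-Gaussian edge constraint (no
continuous parent of a discrete child), the per-node parent limit, and return
acyclic structures.  Ties between equal-gain moves break lexicographically on
(parent, child) for determinism.

Each function accepts an optional ``stats`` dict which is filled with
``candidate_edges`` (distinct candidate edges examined) and ``family_evals``
(family-score evaluations, after caching) for complexity auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CONTINUOUS, DISCRETE, DAGStructure, MixedDataset
from .scoring import PriorHyper, family_score


@dataclass
class SearchConfig:
    """Configuration shared by the four structure-search algorithms."""

    algorithm: str = "greedy"  # k2 | greedy | pheno_centric | annealing
    prior: PriorHyper = field(default_factory=PriorHyper)
    backtracking: bool = False
    proposals: int | None = None  # annealing budget; default n^3
    seed: int = 0
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("k2", "greedy", "pheno_centric", "annealing"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.proposals is not None and self.proposals <= 0:
            raise ValueError("proposal budget must be positive")


class _ScoreCache:
    """Memoized family scores with an evaluation counter."""

    def __init__(self, data: MixedDataset, prior: PriorHyper) -> None:
        self.data = data
        self.prior = prior
        self._cache: dict[tuple[str, frozenset[str]], float] = {}
        self.evals = 0
        self.candidate_edges: set[tuple[str, str]] = set()

    def family(self, child: str, parents: frozenset[str]) -> float:
        key = (child, parents)
        if key not in self._cache:
            self._cache[key] = family_score(self.data, child, parents, self.prior)
            self.evals += 1
        return self._cache[key]

    def gain(self, child: str, parents: frozenset[str], new_parents: frozenset[str]) -> float:
        return self.family(child, new_parents) - self.family(child, parents)


def _edge_legal(data: MixedDataset, parent: str, child: str) -> bool:
    return not (data.kind(parent) == CONTINUOUS and data.kind(child) == DISCRETE)


def _fill_stats(stats: dict | None, cache: _ScoreCache) -> None:
    if stats is not None:
        stats["candidate_edges"] = len(cache.candidate_edges)
        stats["family_evals"] = cache.evals


def k2_order(
    data: MixedDataset,
    phenotype: str | None = None,
    prior: PriorHyper | None = None,
) -> list[str]:
    """Node ordering for the K2 search: phenotype first, then the remaining
    variables by ascending log Bayes factor of dependence on the phenotype
    (most plausibly independent earliest), ties by name.

    Placing the phenotype first lets it parent every other node and take no
    parents itself — the many-children/no-parents topology that predicts best.
    """
    phenotype = phenotype or data.phenotype
    prior = prior or PriorHyper()
    rest = []
    for v in data.names:
        if v == phenotype:
            continue
        log_bf = family_score(data, v, {phenotype}, prior) - family_score(data, v, set(), prior)
        rest.append((log_bf, v))
    rest.sort(key=lambda t: (t[0], t[1]))
    return [phenotype] + [v for _, v in rest]


def _k2_learn_child(
    child: str,
    predecessors: list[str],
    structure: DAGStructure,
    cache: _ScoreCache,
    max_parents: int,
) -> None:
    """Greedy parent selection for one child among its K2 predecessors,
    with an add-triggers-remove swap once the parent limit binds."""
    data = cache.data
    candidates = [p for p in predecessors if _edge_legal(data, p, child)]
    while True:
        parents = frozenset(structure.parents(child))
        free = sorted(set(candidates) - parents)
        best_gain, best_move = 0.0, None
        if len(parents) < max_parents:
            for p in free:
                cache.candidate_edges.add((p, child))
                g = cache.gain(child, parents, parents | {p})
                if g > best_gain or (g == best_gain and best_move and (p, None) < best_move):
                    best_gain, best_move = g, (p, None)
        elif max_parents > 0:
            # at the limit: adding a parent may trigger removal of another
            for p in free:
                cache.candidate_edges.add((p, child))
                for old in sorted(parents):
                    g = cache.gain(child, parents, (parents - {old}) | {p})
                    if g > best_gain:
                        best_gain, best_move = g, (p, old)
        if best_move is None or best_gain <= 0.0:
            return
        p, old = best_move
        if old is not None:
            structure.remove_edge(old, child)
        structure.add_edge(p, child)


def learn_k2(
    data: MixedDataset,
    order: list[str],
    config: SearchConfig,
    stats: dict | None = None,
) -> DAGStructure:
    """K2-style search: parents only from earlier in the order (acyclic by
    construction); continuous-node families learned first, then discrete."""
    if sorted(order) != sorted(data.names):
        raise ValueError("order must be a permutation of the dataset variables")
    cache = _ScoreCache(data, config.prior)
    structure = DAGStructure(data.names)
    position = {v: i for i, v in enumerate(order)}
    cont_children = [v for v in order if data.kind(v) == CONTINUOUS]
    disc_children = [v for v in order if data.kind(v) == DISCRETE]
    for child in cont_children + disc_children:
        predecessors = [p for p in order if position[p] < position[child]]
        _k2_learn_child(child, predecessors, structure, cache, config.prior.max_parents)
    _fill_stats(stats, cache)
    assert all(position[p] < position[c] for p, c in structure.edges)
    return structure


def learn_greedy_exhaustive(
    data: MixedDataset,
    config: SearchConfig,
    stats: dict | None = None,
) -> DAGStructure:
    """Greedy hill-climbing from the empty network: repeatedly apply the
    legal single-edge addition (or, with backtracking, removal) with the
    largest strictly positive score gain; stop when none improves."""
    cache = _ScoreCache(data, config.prior)
    structure = DAGStructure(data.names)
    k = config.prior.max_parents
    while True:
        best_gain, best_move = 0.0, None
        for child in data.names:
            parents = frozenset(structure.parents(child))
            if len(parents) < k:
                for p in data.names:
                    if (
                        p == child
                        or p in parents
                        or not _edge_legal(data, p, child)
                        or structure.has_path(child, p)
                    ):
                        continue
                    cache.candidate_edges.add((p, child))
                    g = cache.gain(child, parents, parents | {p})
                    move = ("add", p, child)
                    if g > best_gain or (g == best_gain and best_move and move < best_move):
                        best_gain, best_move = g, move
            if config.backtracking:
                for p in sorted(parents):
                    g = cache.gain(child, parents, parents - {p})
                    move = ("del", p, child)
                    if g > best_gain or (g == best_gain and best_move and move < best_move):
                        best_gain, best_move = g, move
        if best_move is None or best_gain <= 0.0:
            break
        op, p, c = best_move
        if op == "add":
            structure.add_edge(p, c)
        else:
            structure.remove_edge(p, c)
    _fill_stats(stats, cache)
    return structure


def learn_pheno_centric(
    data: MixedDataset,
    phenotype: str | None = None,
    config: SearchConfig | None = None,
    stats: dict | None = None,
) -> DAGStructure:
    """Markov-blanket search around the phenotype.

    Stage 1 greedily adds phenotype->child edges by score gain; stage 2
    greedily adds co-parents (other variables -> accepted child).  The
    phenotype never receives parents, and every edge touches its blanket.
    """
    config = config or SearchConfig(algorithm="pheno_centric")
    phenotype = phenotype or config.phenotype or data.phenotype
    if data.kind(phenotype) != DISCRETE:
        raise TypeError("phenotype must be discrete")
    cache = _ScoreCache(data, config.prior)
    structure = DAGStructure(data.names)
    k = config.prior.max_parents
    # stage 1: children of the phenotype
    while True:
        best_gain, best_child = 0.0, None
        for v in data.names:
            if v == phenotype or structure.has_edge(phenotype, v):
                continue
            if not _edge_legal(data, phenotype, v) or len(structure.parents(v)) >= k:
                continue
            cache.candidate_edges.add((phenotype, v))
            parents = frozenset(structure.parents(v))
            g = cache.gain(v, parents, parents | {phenotype})
            if g > best_gain or (g == best_gain and best_child and v < best_child):
                best_gain, best_child = g, v
        if best_child is None or best_gain <= 0.0:
            break
        structure.add_edge(phenotype, best_child)
    # stage 2: co-parents of each accepted child
    for child in sorted(structure.children(phenotype)):
        while True:
            parents = frozenset(structure.parents(child))
            if len(parents) >= k:
                break
            best_gain, best_p = 0.0, None
            for p in data.names:
                if (
                    p == child
                    or p in parents
                    or not _edge_legal(data, p, child)
                    or structure.has_path(child, p)
                ):
                    continue
                cache.candidate_edges.add((p, child))
                g = cache.gain(child, parents, parents | {p})
                if g > best_gain or (g == best_gain and best_p and p < best_p):
                    best_gain, best_p = g, p
            if best_p is None or best_gain <= 0.0:
                break
            structure.add_edge(best_p, child)
    assert not structure.parents(phenotype)
    _fill_stats(stats, cache)
    return structure


def learn_simulated_annealing(
    data: MixedDataset,
    config: SearchConfig,
    stats: dict | None = None,
    t0: float | None = None,
    trace: list | None = None,
) -> DAGStructure:
    """Simulated annealing over single-edge moves.

    Uniform random proposals (addition of a legal absent edge or removal of a
    present one); improving moves always accepted, worsening moves with
    probability exp(dScore/T_i).  T_0 defaults to the median |dScore| over 100
    probe proposals from the empty network (overridable via ``t0``); the
    geometric schedule spans the proposal budget, cooling from T_0 down to
    1e-6*T_0 (floored at 1e-8) so short runs still finish cold.  The
    best-scoring structure visited is returned.  ``trace``, if given, collects
    the accepted score deltas in order.
    """
    rng = np.random.default_rng(config.seed)
    cache = _ScoreCache(data, config.prior)
    structure = DAGStructure(data.names)
    names = list(data.names)
    n = len(names)
    k = config.prior.max_parents
    budget = config.proposals if config.proposals is not None else n ** 3

    def propose() -> tuple[str, str, str] | None:
        i, j = rng.integers(0, n), rng.integers(0, n - 1)
        p = names[i]
        c = names[j if j < i else j + 1]
        if structure.has_edge(p, c):
            return ("del", p, c)
        if (
            _edge_legal(data, p, c)
            and len(structure.parents(c)) < k
            and not structure.has_path(c, p)
        ):
            return ("add", p, c)
        return None

    def delta(move: tuple[str, str, str]) -> float:
        op, p, c = move
        parents = frozenset(structure.parents(c))
        new = parents | {p} if op == "add" else parents - {p}
        cache.candidate_edges.add((p, c))
        return cache.gain(c, parents, new)

    if t0 is None:
        probe_deltas = []
        for _ in range(100):
            mv = propose()
            if mv is not None:
                probe_deltas.append(abs(delta(mv)))
        t0 = float(np.median(probe_deltas)) if probe_deltas else 1.0
    t0 = max(t0, 1e-8)

    cool = (1e-6) ** (1.0 / budget)  # reach 1e-6 * T0 by the last proposal
    current = 0.0  # score relative to the empty network
    best_score, best = 0.0, structure.copy()
    temp = t0
    for _ in range(budget):
        mv = propose()
        if mv is not None:
            d = delta(mv)
            if d > 0 or rng.random() < np.exp(d / temp):
                op, p, c = mv
                if op == "add":
                    structure.add_edge(p, c)
                else:
                    structure.remove_edge(p, c)
                current += d
                if trace is not None:
                    trace.append(d)
                if current > best_score:
                    best_score, best = current, structure.copy()
        temp = max(temp * cool, 1e-8)
    _fill_stats(stats, cache)
    return best


def naive_bayes_structure(
    data: MixedDataset,
    phenotype: str | None = None,
    children: list[str] | None = None,
) -> DAGStructure:
    """Phenotype -> every (or the given) variable: the naive-Bayes topology,
    which in practice predicts extremely well despite its simplicity."""
    phenotype = phenotype or data.phenotype
    children = children if children is not None else [v for v in data.names if v != phenotype]
    structure = DAGStructure(data.names)
    for c in children:
        if c != phenotype and _edge_legal(data, phenotype, c):
            structure.add_edge(phenotype, c)
    return structure


def learn_structure(
    data: MixedDataset, config: SearchConfig, stats: dict | None = None
) -> DAGStructure:
    """Dispatch to the configured search algorithm."""
    if config.algorithm == "k2":
        order = k2_order(data, config.phenotype or data.phenotype, config.prior)
        return learn_k2(data, order, config, stats)
    if config.algorithm == "greedy":
        return learn_greedy_exhaustive(data, config, stats)
    if config.algorithm == "pheno_centric":
        return learn_pheno_centric(data, config.phenotype, config, stats)
    return learn_simulated_annealing(data, config, stats)
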