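"""Core data model: typed mixed datasets and conditional Gaussian Bayesian networks.

A conditional Gaussian Bayesian network (CGBN) is a DAG over discrete and
continuous random variables in which

* discrete nodes carry a conditional probability table (CPT) indexed by the
  joint configuration of their (necessarily discrete) parents, and
* continuous nodes are Gaussian with mean linear in their continuous parents,
  the regression parameters (intercept, coefficients, variance) switching with
  the joint configuration of their discrete parents.

Edges from continuous nodes into discrete nodes are structurally forbidden;
this restriction is what keeps exact inference tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISCRETE = "discrete"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one variable: its name, kind and (if discrete) states.

    ``states`` is the ordered tuple of admissible state labels for a discrete
    variable and must be ``None`` for a continuous one.
    """

    name: str
    kind: str
    states: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (DISCRETE, CONTINUOUS):
            raise ValueError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == DISCRETE:
            if not self.states or len(self.states) < 1:
                raise ValueError(f"discrete variable {self.name!r} needs a state list")
            if len(set(self.states)) != len(self.states):
                raise ValueError(f"duplicate states for variable {self.name!r}")
            object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        elif self.states is not None:
            raise ValueError(f"continuous variable {self.name!r} cannot have states")

    @property
    def n_states(self) -> int:
        if self.kind != DISCRETE:
            raise TypeError(f"{self.name!r} is continuous")
        return len(self.states)  # type: ignore[arg-type]


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


class MixedDataset:
    """Complete-case table of typed columns with one designated phenotype.

    Discrete columns are stored as string labels drawn from the variable's
    state list; continuous columns as floats.  Rows with missing cells are not
    representable: construction fails on NaN/empty cells (use
    :meth:`from_frame` to drop them with a logged count).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        variables: Sequence[VariableSpec],
        phenotype: str,
        n_dropped: int = 0,
    ) -> None:
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if list(frame.columns) != names:
            frame = frame.loc[:, names]
        if phenotype not in names:
            raise ValueError(f"phenotype column {phenotype!r} not in dataset")
        self._specs: dict[str, VariableSpec] = {v.name: v for v in variables}
        if self._specs[phenotype].kind != DISCRETE:
            raise ValueError("phenotype must be a discrete variable")
        frame = frame.reset_index(drop=True)
        for v in variables:
            col = frame[v.name]
            if col.isna().any():
                raise ValueError(f"missing values in column {v.name!r}")
            if v.kind == DISCRETE:
                col = col.astype(str)
                bad = set(col.unique()) - set(v.states)  # type: ignore[arg-type]
                if bad:
                    raise ValueError(f"column {v.name!r} has values outside its states: {sorted(bad)}")
                frame[v.name] = col
            else:
                frame[v.name] = pd.to_numeric(col).astype(float)
        self.frame = frame
        self.phenotype = phenotype
        self.n_dropped = n_dropped
        self._codes: dict[str, np.ndarray] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        phenotype: str,
        kind_overrides: Mapping[str, str] | None = None,
        state_orders: Mapping[str, Sequence[str]] | None = None,
    ) -> "MixedDataset":
        """Build a dataset from a raw frame, inferring column kinds.

        Columns containing any non-numeric token become discrete (states in
        first-appearance order unless ``state_orders`` supplies them); fully
        numeric columns become continuous unless overridden.  The phenotype is
        always discrete.  Rows with missing cells are dropped with a logged
        count (complete-case contract).
        """
        kind_overrides = dict(kind_overrides or {})
        state_orders = dict(state_orders or {})
        if phenotype not in frame.columns:
            raise ValueError(f"phenotype column {phenotype!r} absent")
        raw = frame.replace({"": np.nan}).copy()
        n0 = len(raw)
        raw = raw.dropna()
        n_dropped = n0 - len(raw)
        if n_dropped:
            logger.info("dropped %d incomplete rows (complete-case contract)", n_dropped)
        specs = []
        for name in raw.columns:
            col = raw[name]
            tokens = col.astype(str)
            numeric = all(_is_number(t) for t in tokens)
            kind = kind_overrides.get(name, CONTINUOUS if numeric else DISCRETE)
            if name == phenotype:
                kind = DISCRETE
            if kind == DISCRETE:
                if name in state_orders:
                    states = tuple(str(s) for s in state_orders[name])
                else:
                    states = tuple(dict.fromkeys(tokens))  # first appearance
                specs.append(VariableSpec(name, DISCRETE, states))
                raw[name] = tokens
            else:
                if numeric:
                    distinct = tokens.nunique()
                    vals = pd.to_numeric(col)
                    if (vals == vals.round()).all() and distinct <= 10:
                        logger.info(
                            "column %r is integer-coded with %d distinct values; possibly discrete",
                            name, distinct,
                        )
                specs.append(VariableSpec(name, CONTINUOUS))
        return cls(raw, specs, phenotype, n_dropped=n_dropped)

    # -- accessors ----------------------------------------------------------

    @property
    def variables(self) -> tuple[VariableSpec, ...]:
        return tuple(self._specs.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    @property
    def n(self) -> int:
        return len(self.frame)

    def var(self, name: str) -> VariableSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def kind(self, name: str) -> str:
        return self.var(name).kind

    @property
    def discrete_names(self) -> tuple[str, ...]:
        return tuple(n for n, v in self._specs.items() if v.kind == DISCRETE)

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(n for n, v in self._specs.items() if v.kind == CONTINUOUS)

    def codes(self, name: str) -> np.ndarray:
        """Integer state codes (in declared state order) for a discrete column."""
        if name not in self._codes:
            spec = self.var(name)
            if spec.kind != DISCRETE:
                raise TypeError(f"{name!r} is continuous")
            cat = pd.Categorical(self.frame[name], categories=spec.states)
            self._codes[name] = np.asarray(cat.codes, dtype=np.int64)
        return self._codes[name]

    def values(self, name: str) -> np.ndarray:
        if self.var(name).kind != CONTINUOUS:
            raise TypeError(f"{name!r} is discrete")
        return self.frame[name].to_numpy(dtype=float)

    def take(self, indices: Sequence[int] | np.ndarray) -> "MixedDataset":
        """Row subset (or resample) keeping the declared variable specs."""
        sub = self.frame.iloc[np.asarray(indices)].reset_index(drop=True)
        return MixedDataset(sub, self.variables, self.phenotype)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MixedDataset(n={self.n}, discrete={len(self.discrete_names)}, "
            f"continuous={len(self.continuous_names)}, phenotype={self.phenotype!r})"
        )


class DAGStructure:
    """Directed graph over named nodes with parent/child adjacency.

    Acyclicity is not enforced on mutation; callers check with
    :func:`is_acyclic` (the structure searches do so for every candidate).
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()) -> None:
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self.nodes}
        for p, c in edges:
            self.add_edge(p, c)

    # -- mutation ------------------------------------------------------------

    def add_edge(self, parent: str, child: str) -> None:
        if parent not in self._parents or child not in self._parents:
            raise KeyError(f"edge ({parent!r}, {child!r}) references undeclared node")
        if parent == child:
            raise ValueError("self-loops are not allowed")
        self._parents[child].add(parent)
        self._children[parent].add(child)

    def remove_edge(self, parent: str, child: str) -> None:
        self._parents[child].discard(parent)
        self._children[parent].discard(child)

    # -- queries -------------------------------------------------------------

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, c) for c, ps in self._parents.items() for p in ps)

    def has_edge(self, parent: str, child: str) -> bool:
        return parent in self._parents.get(child, ())

    def parents(self, node: str) -> frozenset[str]:
        if node not in self._parents:
            raise KeyError(f"unknown node {node!r}")
        return frozenset(self._parents[node])

    def children(self, node: str) -> frozenset[str]:
        if node not in self._children:
            raise KeyError(f"unknown node {node!r}")
        return frozenset(self._children[node])

    def has_path(self, src: str, dst: str) -> bool:
        """True iff a directed path src -> ... -> dst exists (DFS)."""
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self._children[u])
        return False

    def copy(self) -> "DAGStructure":
        return DAGStructure(self.nodes, self.edges)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        ready = [n for n in self.nodes if indeg[n] == 0]
        while ready:
            u = ready.pop()
            order.append(u)
            for c in sorted(self._children[u]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a directed cycle")
        return order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAGStructure):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"DAGStructure({len(self.nodes)} nodes, {len(self.edges)} edges)"


def is_acyclic(structure: DAGStructure) -> bool:
    """Depth-first search three-colour cycle check; pure."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in structure.nodes}
    for root in structure.nodes:
        if colour[root] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(root, iter(sorted(structure.children(root))))]
        colour[root] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    return False
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(sorted(structure.children(nxt)))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
    return True


def validate_cg_constraints(
    structure: DAGStructure, variables: Sequence[VariableSpec]
) -> list[tuple[str, str]]:
    """Every continuous -> discrete edge, as (parent, child) violations."""
    kind = {v.name: v.kind for v in variables}
    out = []
    for p, c in sorted(structure.edges):
        if kind[p] == CONTINUOUS and kind[c] == DISCRETE:
            out.append((p, c))
    return out


def markov_blanket(structure: DAGStructure, node: str) -> set[str]:
    """Parents, children and the children's other parents of ``node``."""
    blanket = set(structure.parents(node)) | set(structure.children(node))
    for child in structure.children(node):
        blanket |= structure.parents(child)
    blanket.discard(node)
    return blanket


def parent_configurations(
    structure: DAGStructure, node: str, variables: Sequence[VariableSpec]
) -> list[tuple[str, ...]]:
    """Ordered discrete-parent state combinations for ``node``'s tables.

    Parents are sorted by name; each parent's states keep declared order; the
    product is row-major (first parent varies slowest).  A node with no
    discrete parents has the single empty configuration ``()``.
    """
    spec = {v.name: v for v in variables}
    disc_parents = sorted(p for p in structure.parents(node) if spec[p].kind == DISCRETE)
    if not disc_parents:
        return [()]
    return list(itertools.product(*(spec[p].states for p in disc_parents)))


# -- fitted-network parameter containers -------------------------------------


@dataclass
class DiscreteNodeParams:
    """CPT for a discrete node: one probability row per parent configuration.

    ``parents`` are the node's discrete parents sorted by name; rows of
    ``cpt`` follow :func:`parent_configurations` order; ``counts`` retains the
    observed N_ijk used in fitting/scoring.
    """

    parents: tuple[str, ...]
    states: tuple[str, ...]
    cpt: np.ndarray  # (q, r)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cpt = np.asarray(self.cpt, dtype=float)
        if self.cpt.ndim != 2 or self.cpt.shape[1] != len(self.states):
            raise ValueError("CPT shape must be (q, n_states)")
        if (self.cpt < 0).any():
            raise ValueError("negative CPT entries")
        if not np.allclose(self.cpt.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("CPT rows must sum to 1")


@dataclass
class CLGNodeParams:
    """Conditional linear Gaussian parameters for a continuous node.

    Per discrete-parent configuration j (rows follow
    :func:`parent_configurations` order): intercept beta0_j, coefficient
    vector beta_j over ``cont_parents`` (sorted by name), variance sigma2_j.
    """

    disc_parents: tuple[str, ...]
    cont_parents: tuple[str, ...]
    intercepts: np.ndarray  # (q,)
    coefs: np.ndarray       # (q, m)
    variances: np.ndarray   # (q,)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float).reshape(
            len(self.intercepts), len(self.cont_parents)
        )
        self.variances = np.asarray(self.variances, dtype=float)
        if (self.variances <= 0).any():
            raise ValueError("variances must be strictly positive")


@dataclass
class CGBayesNet:
    """A fitted CGBN: structure plus per-node parameters."""

    structure: DAGStructure
    variables: tuple[VariableSpec, ...]
    params: dict[str, DiscreteNodeParams | CLGNodeParams]
    phenotype: str | None = None
    _spec_map: dict[str, VariableSpec] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self._spec_map = {v.name: v for v in self.variables}
        for node in self.structure.nodes:
            if node not in self.params:
                raise ValueError(f"missing parameters for node {node!r}")
        viol = validate_cg_constraints(self.structure, self.variables)
        if viol:
            raise ValueError(f"continuous->discrete edges: {viol}")

    def var(self, name: str) -> VariableSpec:
        return self._spec_map[name]

    def kind(self, name: str) -> str:
        return self._spec_map[name].kind
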