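"""Bootstrap edge-frequency estimation and consensus-network construction.

A structure search is repeated on bootstrap resamples of the rows; each
directed edge's inclusion fraction across resamples measures its support.  A
consensus network is then grown from the empty graph by adding edges in
descending frequency (skipping any that would create a cycle or violate the
conditional-Gaussian constraint), recording cross-validated AUC after each
addition so the point of diminishing returns can be read off the sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model import CONTINUOUS, DISCRETE, DAGStructure, MixedDataset, is_acyclic
from .search import SearchConfig, learn_structure

logger = logging.getLogger(__name__)


@dataclass
class EdgeFrequencyTable:
    frequencies: dict[tuple[str, str], float]
    B: int

    def ranked(self) -> list[tuple[tuple[str, str], float]]:
        """Edges sorted by descending frequency, ties by edge name."""
        return sorted(self.frequencies.items(), key=lambda t: (-t[1], t[0]))


def bootstrap_networks(
    data: MixedDataset,
    config: SearchConfig,
    B: int = 25,
    seed: int = 0,
) -> EdgeFrequencyTable:
    """Learn one structure per bootstrap resample; return per-edge inclusion
    fractions.  A resample missing a phenotype class is redrawn (logged)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    phenotype = config.phenotype or data.phenotype
    n_classes = data.var(phenotype).n_states
    counts: dict[tuple[str, str], int] = {}
    for b in range(B):
        while True:
            idx = rng.integers(0, data.n, size=data.n)
            if len(np.unique(data.codes(phenotype)[idx])) == n_classes:
                break
            logger.info("bootstrap resample %d lost a phenotype class; redrawn", b)
        sample = data.take(idx)
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        structure = learn_structure(sample, cfg)
        for edge in structure.edges:
            counts[edge] = counts.get(edge, 0) + 1
    freqs = {e: c / B for e, c in counts.items()}
    return EdgeFrequencyTable(freqs, B)


@dataclass
class ConsensusStep:
    structure: DAGStructure
    edge: tuple[str, str]
    frequency: float
    cv_auc: float


def consensus_network(
    freqs: EdgeFrequencyTable,
    data: MixedDataset,
    phenotype: str | None = None,
    max_edges: int | None = None,
    config: SearchConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> list[ConsensusStep]:
    """Grow nested consensus structures by descending edge frequency.

    Cycle-inducing or CG-violating edges are passed over (the frequency list
    continues); after each accepted edge, parameters are refit per CV fold on
    the fixed structure and the pooled CV AUC recorded.
    """
    from .evaluation import cross_validate

    if not freqs.frequencies:
        raise ValueError("empty edge-frequency table")
    config = config or SearchConfig()
    phenotype = phenotype or config.phenotype or data.phenotype
    kind = {v.name: v.kind for v in data.variables}
    structure = DAGStructure(data.names)
    steps: list[ConsensusStep] = []
    for (p, c), f in freqs.ranked():
        if max_edges is not None and len(steps) >= max_edges:
            break
        if kind[p] == CONTINUOUS and kind[c] == DISCRETE:
            continue
        if len(structure.parents(c)) >= config.prior.max_parents:
            continue
        structure.add_edge(p, c)
        if not is_acyclic(structure):
            structure.remove_edge(p, c)
            continue
        cv = cross_validate(
            data, replace(config, phenotype=phenotype), folds=folds, seed=seed,
            structure=structure.copy(),
        )
        steps.append(ConsensusStep(structure.copy(), (p, c), f, cv.pooled_auc))
    return steps
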