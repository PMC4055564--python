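"""Shared fixtures: hand-built small networks and dataset helpers."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from cgbn.model import (
    CGBayesNet,
    CLGNodeParams,
    DAGStructure,
    DiscreteNodeParams,
    MixedDataset,
    VariableSpec,
)


def make_dataset(columns: dict, phenotype: str, specs: list[VariableSpec]) -> MixedDataset:
    return MixedDataset(pd.DataFrame(columns), specs, phenotype)


@pytest.fixture
def gaussian_naive_net() -> CGBayesNet:
    """Uniform binary phenotype with one Gaussian child: X | pheno ~ N(-1,1)/N(+1,1)."""
    vs = (
        VariableSpec("phenotype", "discrete", ("neg", "pos")),
        VariableSpec("X", "continuous"),
    )
    st = DAGStructure(("phenotype", "X"), [("phenotype", "X")])
    params = {
        "phenotype": DiscreteNodeParams((), ("neg", "pos"), np.array([[0.5, 0.5]])),
        "X": CLGNodeParams(
            ("phenotype",), (), np.array([-1.0, 1.0]), np.zeros((2, 0)), np.array([1.0, 1.0])
        ),
    }
    return CGBayesNet(st, vs, params, phenotype="phenotype")


@pytest.fixture
def cpt_naive_net() -> CGBayesNet:
    """Uniform binary phenotype with one binary child: P(D=1 | pheno) = (0.9, 0.2)."""
    vs = (
        VariableSpec("phenotype", "discrete", ("a", "b")),
        VariableSpec("D", "discrete", ("1", "2")),
    )
    st = DAGStructure(("phenotype", "D"), [("phenotype", "D")])
    params = {
        "phenotype": DiscreteNodeParams((), ("a", "b"), np.array([[0.5, 0.5]])),
        "D": DiscreteNodeParams(("phenotype",), ("1", "2"), np.array([[0.9, 0.1], [0.2, 0.8]])),
    }
    return CGBayesNet(st, vs, params, phenotype="phenotype")


def strong_five_node_net() -> CGBayesNet:
    """Five-node network with a strong, unambiguous phenotype Markov blanket.

    phenotype -> C1, C2 (intercepts +/-1.5, unit variance) and
    phenotype -> D2 (CPT rows (0.9,0.1)/(0.1,0.9)); C3 is isolated noise.
    True blanket of the phenotype: {C1, C2, D2}.
    """
    vs = (
        VariableSpec("phenotype", "discrete", ("ctrl", "case")),
        VariableSpec("D2", "discrete", ("1", "2")),
        VariableSpec("C1", "continuous"),
        VariableSpec("C2", "continuous"),
        VariableSpec("C3", "continuous"),
    )
    st = DAGStructure(
        [v.name for v in vs],
        [("phenotype", "C1"), ("phenotype", "C2"), ("phenotype", "D2")],
    )
    params = {
        "phenotype": DiscreteNodeParams((), ("ctrl", "case"), np.array([[0.5, 0.5]])),
        "D2": DiscreteNodeParams(
            ("phenotype",), ("1", "2"), np.array([[0.9, 0.1], [0.1, 0.9]])
        ),
        "C1": CLGNodeParams(
            ("phenotype",), (), np.array([-1.5, 1.5]), np.zeros((2, 0)), np.array([1.0, 1.0])
        ),
        "C2": CLGNodeParams(
            ("phenotype",), (), np.array([1.0, -2.0]), np.zeros((2, 0)), np.array([1.0, 1.0])
        ),
        "C3": CLGNodeParams((), (), np.array([0.0]), np.zeros((1, 0)), np.array([1.0])),
    }
    return CGBayesNet(st, vs, params, phenotype="phenotype")


@pytest.fixture
def strong_net() -> CGBayesNet:
    return strong_five_node_net()
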